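"""Antibiotic-resistance-gene census with detection-limit arithmetic.

ARGs are detected at three confidence tiers — a sensitive profile search
(SENSITIVE), a protein-homology search (HOMOLOGY), and a stringent search
against experimentally confirmed resistance genes (CONFIRMED).  The tiers
are merged per gene; CONFIRMED is independent of the other two (a confirmed
ARG can be missed by both broader searches, and the sensitive tier includes
transporter families such as ABC efflux pumps that the homology database
does not cover and that are flagged low-confidence here).

The census then attributes ARG-positive contigs to compartments and mobile
element classes, and converts counts into per-gene and per-Mb rates, genome
extrapolations (3-Mb bacterial genome, 30-kb / 30-ORF phage genome) and —
when a compartment has zero ARGs — detection limits using a pseudo-count of
one: the claim is then an upper bound, 1/denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .activity import ActivityRecord
from .io import EvidenceRecord, EvidenceSource
from .triage import ClassificationRecord, Label, VIRAL_LABELS

__all__ = [
    "Tier",
    "ArgHit",
    "DensityReport",
    "TierConfig",
    "call_args",
    "classify_arg_contigs",
    "density_report",
    "enrichment_ratio",
    "confirmed_hits",
]


class Tier(str, Enum):
    SENSITIVE = "SENSITIVE"
    HOMOLOGY = "HOMOLOGY"
    CONFIRMED = "CONFIRMED"


_SOURCE_TIER = {
    EvidenceSource.ARG_PROFILE: Tier.SENSITIVE,
    EvidenceSource.ARG_HOMOLOGY: Tier.HOMOLOGY,
    EvidenceSource.ARG_CONFIRMED: Tier.CONFIRMED,
}

#: ARG families reported by the sensitive profile tier that are generic
#: transporters rather than dedicated resistance genes.
LOW_CONFIDENCE_FAMILIES = frozenset({"ABC_efflux", "RND_efflux", "MFS_efflux", "tet_MFS_efflux"})


@dataclass
class ArgHit:
    """One merged ARG call on one gene of one contig."""

    contig_id: str
    gene_index: int
    arg_name: str
    drug_class: str = ""
    tiers: set[Tier] = field(default_factory=set)
    e_value: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ValueError(f"{self.contig_id}: ArgHit needs at least one tier")


@dataclass
class TierConfig:
    low_confidence_families: frozenset[str] = LOW_CONFIDENCE_FAMILIES
    #: tier priority used to pick the reported gene name when sources disagree
    name_priority: tuple[Tier, ...] = (Tier.CONFIRMED, Tier.SENSITIVE, Tier.HOMOLOGY)


def call_args(
    evidence: Sequence[EvidenceRecord],
    tier_config: TierConfig | None = None,
) -> list[ArgHit]:
    """Merge ARG evidence rows into one hit per (contig, gene).

    Tiers union across sources; the reported name follows the configured
    tier priority; the E-value is the best (lowest) observed.  Transporter
    families are flagged ``low_confidence``.  Merging is independent of the
    evidence row order.
    """
    cfg = tier_config or TierConfig()
    per_gene: dict[tuple[str, int], dict[Tier, list[EvidenceRecord]]] = {}
    for rec in evidence:
        tier = _SOURCE_TIER.get(rec.source)
        if tier is None:
            continue
        if rec.gene_index is None:
            raise ValueError(f"{rec.contig_id}: ARG evidence without gene_index")
        per_gene.setdefault((rec.contig_id, rec.gene_index), {}).setdefault(tier, []).append(rec)

    hits: list[ArgHit] = []
    for (cid, gi) in sorted(per_gene):
        by_tier = per_gene[(cid, gi)]
        name = ""
        drug = ""
        for tier in cfg.name_priority:
            rows = by_tier.get(tier)
            if rows:
                best = min(rows, key=lambda r: (r.e_value if r.e_value is not None else float("inf"), r.category))
                name = best.category
                drug = "" if best.subject_type.value == "NA" else best.subject_type.value
                break
        evals = [r.e_value for rows in by_tier.values() for r in rows if r.e_value is not None]
        names = {r.category for rows in by_tier.values() for r in rows}
        hits.append(
            ArgHit(
                contig_id=cid,
                gene_index=gi,
                arg_name=name,
                drug_class=drug,
                tiers=set(by_tier),
                e_value=min(evals) if evals else None,
                low_confidence=bool(names & cfg.low_confidence_families),
            )
        )
    return hits


def confirmed_hits(hits: Iterable[ArgHit]) -> list[ArgHit]:
    """Stringent-tier hits, excluding low-confidence transporter families."""
    return [h for h in hits if Tier.CONFIRMED in h.tiers and not h.low_confidence]


_LABEL_GROUP = {
    Label.PHAGE: "viral",
    Label.INOVIRUS: "viral",
    Label.EUK_VIRUS: "viral",
    Label.BACTERIAL: "bacterial",
    Label.PLASMID: "plasmid",
    Label.UNCLASSIFIED: "unclassified",
}


@dataclass
class ArgCrossTab:
    """ARG-positive contig counts by class x compartment x activity, plus
    the fraction of viral contigs that are ARG-positive per compartment."""

    table: pd.DataFrame  # index (group, compartment, status), column 'contigs'
    viral_fraction: dict[str, float]  # compartment -> fraction (of viral contigs)
    n_viral: dict[str, int]  # compartment -> viral contig universe size


def classify_arg_contigs(
    args: Sequence[ArgHit],
    classes: Sequence[ClassificationRecord] = (),
    activity: Sequence[ActivityRecord] = (),
) -> ArgCrossTab:
    """Attribute ARG-positive contigs to contig classes and compartments.

    Virome contigs take their cascade label; microbiome contigs are viral
    when flagged viral-P (with their active/dormant status) and bacterial
    otherwise.  Also reports, per compartment, the ARG-positive fraction of
    the viral contig universe (e.g. 3 of 16 940 viral-P contigs = 0.02 %).
    """
    by_id = {r.contig_id: r for r in classes}
    act_by_id = {r.contig_id: r for r in activity}
    arg_contigs = sorted({h.contig_id for h in args})

    rows: list[tuple[str, str, str]] = []
    for cid in arg_contigs:
        if cid in by_id:
            rows.append((_LABEL_GROUP[by_id[cid].label], "virome", "NA"))
        elif cid in act_by_id:
            rec = act_by_id[cid]
            group = "viral" if rec.is_viral_p else "bacterial"
            rows.append((group, "microbiome", rec.status.value.lower() if rec.is_viral_p else "NA"))
        else:
            raise ValueError(f"ARG-positive contig {cid!r} missing from both universes")

    idx = pd.MultiIndex.from_tuples(rows or [], names=["group", "compartment", "status"])
    table = (
        pd.DataFrame(index=idx).groupby(level=[0, 1, 2]).size().to_frame("contigs")
        if rows
        else pd.DataFrame(columns=["contigs"])
    )

    n_viral = {
        "virome": sum(1 for r in classes if r.label in VIRAL_LABELS),
        "microbiome": sum(1 for r in activity if r.is_viral_p),
    }
    viral_arg = {
        "virome": sum(
            1 for cid in arg_contigs if cid in by_id and by_id[cid].label in VIRAL_LABELS
        ),
        "microbiome": sum(
            1 for cid in arg_contigs if cid in act_by_id and act_by_id[cid].is_viral_p
        ),
    }
    viral_fraction = {
        comp: (viral_arg[comp] / n_viral[comp]) if n_viral[comp] else 0.0
        for comp in ("virome", "microbiome")
    }
    return ArgCrossTab(table=table, viral_fraction=viral_fraction, n_viral=n_viral)


@dataclass
class DensityReport:
    """Compartment-level ARG rates and (for zero counts) detection limits."""

    compartment: str
    n_args: int
    n_genes: int
    assembled_mb: float
    n_contigs: int | None = None
    per_gene: float = 0.0  # ARG per gene
    per_mb: float = 0.0  # ARG per Mb of assembled sequence
    per_bacterial_genome: float = 0.0  # assuming a 3-Mb bacterial genome
    per_phage_genome_bound: float | None = None  # assuming 30 ORFs / 30-kb genome
    detection_limit_per_mb: float | None = None
    detection_limit_fraction: float | None = None  # % of contigs
    is_upper_bound: bool = False


def density_report(
    args: Sequence[ArgHit],
    n_genes: int,
    assembled_mb: float,
    compartment: str,
    n_contigs: int | None = None,
    genome_sizes: tuple[float, float] = (3.0, 0.030),
    orfs_per_phage_genome: int = 30,
    zero_bound: int = 1,
) -> DensityReport:
    """ARG density of one compartment, with zero-count detection limits.

    ``genome_sizes`` holds the (bacterial, phage) genome sizes in Mb used
    for extrapolation.  With zero ARGs the per-gene, per-Mb and per-contig
    figures become upper bounds computed with ``zero_bound`` pseudo-counts:
    the phage-genome bound is the per-ORF bound times the ORFs per phage
    genome (30 ORFs on a 30-kb genome, i.e. one gene per kb).
    """
    if assembled_mb <= 0:
        raise ValueError("assembled_mb must be positive")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    bact_mb, phage_mb = genome_sizes
    n_args = len(args)
    rep = DensityReport(
        compartment=compartment,
        n_args=n_args,
        n_genes=n_genes,
        assembled_mb=assembled_mb,
        n_contigs=n_contigs,
    )
    if n_args > 0:
        rep.per_gene = n_args / n_genes
        rep.per_mb = n_args / assembled_mb
        rep.per_bacterial_genome = rep.per_mb * bact_mb
        rep.per_phage_genome_bound = rep.per_gene * orfs_per_phage_genome
    else:
        rep.is_upper_bound = True
        rep.per_gene = zero_bound / n_genes
        rep.per_mb = zero_bound / assembled_mb
        rep.per_bacterial_genome = rep.per_mb * bact_mb
        rep.per_phage_genome_bound = rep.per_gene * orfs_per_phage_genome
        rep.detection_limit_per_mb = zero_bound / assembled_mb
        if n_contigs:
            rep.detection_limit_fraction = 100.0 * zero_bound / n_contigs
    return rep


def enrichment_ratio(bacterial: DensityReport, viral: DensityReport) -> float:
    """How many times likelier an ARG is per bacterial genome than per phage
    genome (viral side usually an upper bound, so the ratio is a floor)."""
    if not viral.per_phage_genome_bound:
        raise ValueError("viral report lacks a per-phage-genome figure")
    return bacterial.per_bacterial_genome / viral.per_phage_genome_bound
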