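"""Two-pass priority cascade classifying virome contigs.

Virome contigs are labelled phage / inovirus / eukaryotic virus / bacterial /
plasmid / unclassified by a priority-ordered sequence of evidence stages, each
stage only seeing contigs that earlier stages left unlabelled:

* ``SORTER`` — a viral-sorter verdict (any category accepted) labels PHAGE;
* ``INOVIRUS`` — a filamentous-phage detector verdict labels INOVIRUS;
* ``HOMOLOGY_PHROG`` — nucleotide homology (E < 1e-16) proposes a label from
  the subject taxon, but a contig whose proteins look phage-like under the
  profile rule is labelled PHAGE even when its best nucleotide hit is
  bacterial (bacterial hits can be prophages carried in bacterial genomes);
* ``SECONDARY`` — a fallback classifier verdict labels PHAGE or EUK_VIRUS.

Contigs are split by total abundance first: the high-abundance pass (total
RPKM above ``rpkm_cut``) runs all four stages, the low-abundance pass runs
only SECONDARY and INOVIRUS.  Inoviruses count as viral (and as phages) in
all tallies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from ._util import round_half_away
from .io import ContigRecord, EvidenceRecord, EvidenceSource, SubjectType

__all__ = [
    "Label",
    "Stage",
    "PassId",
    "ClassificationRecord",
    "StageTally",
    "TriageConfig",
    "phrog_rule",
    "apply_stage",
    "run_cascade",
    "tally",
]


class Label(str, Enum):
    PHAGE = "PHAGE"
    INOVIRUS = "INOVIRUS"
    EUK_VIRUS = "EUK_VIRUS"
    BACTERIAL = "BACTERIAL"
    PLASMID = "PLASMID"
    UNCLASSIFIED = "UNCLASSIFIED"


VIRAL_LABELS = frozenset({Label.PHAGE, Label.INOVIRUS, Label.EUK_VIRUS})
PHAGE_LABELS = frozenset({Label.PHAGE, Label.INOVIRUS})


class Stage(str, Enum):
    SORTER = "SORTER"
    INOVIRUS = "INOVIRUS"
    HOMOLOGY_PHROG = "HOMOLOGY_PHROG"
    SECONDARY = "SECONDARY"
    NONE = "NONE"


class PassId(str, Enum):
    HIGH_ABUNDANCE = "HIGH_ABUNDANCE"
    LOW_ABUNDANCE = "LOW_ABUNDANCE"


@dataclass
class ClassificationRecord:
    contig_id: str
    label: Label
    stage: Stage
    pass_id: PassId
    clade: str | None = None

    def __post_init__(self) -> None:
        if (self.label is Label.UNCLASSIFIED) != (self.stage is Stage.NONE):
            raise ValueError(
                f"{self.contig_id}: label UNCLASSIFIED iff stage NONE "
                f"(got {self.label.value} @ {self.stage.value})"
            )


@dataclass
class TriageConfig:
    """Thresholds of the cascade, all read from the published procedure
    except ``secondary_map`` whose category naming is a package default."""

    rpkm_cut: float = 100.0
    e_nucl: float = 1e-16
    e_phrog: float = 1e-12
    phrog_min_orfs: int = 5
    phrog_fraction: float = 0.35
    #: fallback-stage category string -> label; unknown categories use the
    #: evidence row's subject_type, then default to PHAGE.
    secondary_map: dict[str, Label] = field(
        default_factory=lambda: {
            "phage": Label.PHAGE,
            "prophage": Label.PHAGE,
            "virus": Label.EUK_VIRUS,
            "euk_virus": Label.EUK_VIRUS,
            "eukaryotic_virus": Label.EUK_VIRUS,
        }
    )


def phrog_rule(
    n_orfs: int,
    n_profile_hits: int,
    e_values: Sequence[float],
    e_cut: float = 1e-12,
    min_orfs: int = 5,
    fraction: float = 0.35,
) -> bool:
    """Phage-protein-profile rule: >= ``min_orfs`` ORFs and >= ``fraction``
    of them with a profile hit below ``e_cut``.

    ``e_values`` are the E-values of the profile hits (one per hit ORF);
    only hits with E < e_cut qualify.  The fraction test is inclusive and
    computed against all called ORFs.
    """
    if not (0 <= n_profile_hits <= n_orfs):
        raise ValueError("need 0 <= n_profile_hits <= n_orfs")
    if len(e_values) != n_profile_hits:
        raise ValueError("e_values must have one entry per profile hit")
    if n_orfs < min_orfs:
        return False
    qualified = sum(1 for e in e_values if e < e_cut)
    return qualified / n_orfs >= fraction


_SUBJECT_LABEL = {
    SubjectType.PHAGE: Label.PHAGE,
    SubjectType.EUK_VIRUS: Label.EUK_VIRUS,
    SubjectType.BACTERIAL: Label.BACTERIAL,
    SubjectType.PLASMID: Label.PLASMID,
}


def _by_contig(
    evidence: Iterable[EvidenceRecord], source: EvidenceSource
) -> dict[str, list[EvidenceRecord]]:
    out: dict[str, list[EvidenceRecord]] = {}
    for rec in evidence:
        if rec.source is source:
            out.setdefault(rec.contig_id, []).append(rec)
    return out


def _best_row(rows: list[EvidenceRecord]) -> EvidenceRecord:
    """Deterministic duplicate resolution: lowest E-value wins (None last),
    ties broken by category then subject type."""
    return min(
        rows,
        key=lambda r: (
            r.e_value if r.e_value is not None else float("inf"),
            r.category,
            r.subject_type.value,
        ),
    )


def _secondary_label(rec: EvidenceRecord, config: TriageConfig) -> Label:
    lab = config.secondary_map.get(rec.category.strip().lower())
    if lab is not None:
        return lab
    if rec.subject_type in (SubjectType.PHAGE, SubjectType.EUK_VIRUS):
        return _SUBJECT_LABEL[rec.subject_type]
    return Label.PHAGE


def apply_stage(
    contig_ids: Iterable[str],
    evidence: Sequence[EvidenceRecord],
    stage: Stage,
    config: TriageConfig | None = None,
    orf_counts: Mapping[str, int] | None = None,
) -> dict[str, Label]:
    """Run one cascade stage over still-unlabelled contigs.

    Returns labels only for contigs the stage decides; the order of evidence
    rows never influences the outcome (duplicates resolve to the lowest
    E-value).  ``orf_counts`` is required for the HOMOLOGY_PHROG stage.
    """
    config = config or TriageConfig()
    ids = list(contig_ids)
    idset = set(ids)
    labels: dict[str, Label] = {}

    if stage is Stage.SORTER:
        for cid in _by_contig(evidence, EvidenceSource.SORTER):
            if cid in idset:
                labels[cid] = Label.PHAGE  # all sorter categories accepted
    elif stage is Stage.INOVIRUS:
        for cid in _by_contig(evidence, EvidenceSource.INOVIRUS):
            if cid in idset:
                labels[cid] = Label.INOVIRUS
    elif stage is Stage.SECONDARY:
        for cid, rows in _by_contig(evidence, EvidenceSource.SECONDARY).items():
            if cid in idset:
                labels[cid] = _secondary_label(_best_row(rows), config)
    elif stage is Stage.HOMOLOGY_PHROG:
        if orf_counts is None:
            raise ValueError("HOMOLOGY_PHROG stage needs per-contig orf_counts")
        nucl = _by_contig(evidence, EvidenceSource.NUCL_HOMOLOGY)
        prot = _by_contig(evidence, EvidenceSource.PROT_PROFILE)
        for cid in ids:
            candidate: Label | None = None
            rows = [
                r for r in nucl.get(cid, [])
                if r.e_value is not None and r.e_value < config.e_nucl
            ]
            if rows:
                candidate = _SUBJECT_LABEL.get(_best_row(rows).subject_type)
            hits = [r.e_value for r in prot.get(cid, []) if r.e_value is not None]
            phrog_ok = phrog_rule(
                n_orfs=orf_counts.get(cid, 0),
                n_profile_hits=len(hits),
                e_values=hits,
                e_cut=config.e_phrog,
                min_orfs=config.phrog_min_orfs,
                fraction=config.phrog_fraction,
            ) if orf_counts.get(cid, 0) >= len(hits) else False
            if candidate is None:
                if phrog_ok:
                    labels[cid] = Label.PHAGE
            elif candidate is Label.BACTERIAL and phrog_ok:
                labels[cid] = Label.PHAGE  # prophage override
            else:
                labels[cid] = candidate
    else:
        raise ValueError(f"cannot apply stage {stage}")
    return labels


_HIGH_STAGES = (Stage.SORTER, Stage.INOVIRUS, Stage.HOMOLOGY_PHROG, Stage.SECONDARY)
_LOW_STAGES = (Stage.SECONDARY, Stage.INOVIRUS)


def run_cascade(
    contigs: Sequence[ContigRecord],
    evidence: Sequence[EvidenceRecord],
    abundance: Mapping[str, float],
    rpkm_cut: float | None = None,
    *,
    orf_counts: Mapping[str, int] | None = None,
    config: TriageConfig | None = None,
    clades: Mapping[str, str] | None = None,
) -> list[ClassificationRecord]:
    """Classify every contig, recording the deciding stage and pass.

    ``abundance`` maps contig_id to total RPKM summed over samples; contigs
    strictly above ``rpkm_cut`` form the high-abundance pass.  ``orf_counts``
    is computed from contig sequences when not supplied.
    """
    config = config or TriageConfig()
    if rpkm_cut is not None:
        config = TriageConfig(**{**config.__dict__, "rpkm_cut": rpkm_cut})
    missing = [c.contig_id for c in contigs if c.contig_id not in abundance]
    if missing:
        raise ValueError(f"contigs missing from abundance map: {missing[:5]}")
    if orf_counts is None:
        from .io import call_orfs

        orf_counts = {
            c.contig_id: call_orfs(c).n_orfs
            for c in contigs
            if c.sequence is not None
        }

    out: list[ClassificationRecord] = []
    for pass_id, stages in (
        (PassId.HIGH_ABUNDANCE, _HIGH_STAGES),
        (PassId.LOW_ABUNDANCE, _LOW_STAGES),
    ):
        if pass_id is PassId.HIGH_ABUNDANCE:
            members = [c for c in contigs if abundance[c.contig_id] > config.rpkm_cut]
        else:
            members = [c for c in contigs if abundance[c.contig_id] <= config.rpkm_cut]
        unlabeled = [c.contig_id for c in members]
        decided: dict[str, tuple[Label, Stage]] = {}
        for stage in stages:
            stage_labels = apply_stage(unlabeled, evidence, stage, config, orf_counts)
            for cid, lab in stage_labels.items():
                decided[cid] = (lab, stage)
            unlabeled = [cid for cid in unlabeled if cid not in decided]
        for c in members:
            lab, stg = decided.get(c.contig_id, (Label.UNCLASSIFIED, Stage.NONE))
            out.append(
                ClassificationRecord(
                    contig_id=c.contig_id,
                    label=lab,
                    stage=stg,
                    pass_id=pass_id,
                    clade=(clades or {}).get(c.contig_id),
                )
            )
    return out


@dataclass
class StageTally:
    """Per-(pass, stage, label) counts plus the derived accounting."""

    counts: dict[tuple[PassId, Stage, Label], int]

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {key}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def _label_total(self, labels: frozenset[Label] | set[Label]) -> int:
        return sum(n for (_, _, lab), n in self.counts.items() if lab in labels)

    @property
    def unclassified(self) -> int:
        return self._label_total({Label.UNCLASSIFIED})

    @property
    def classified(self) -> int:
        return self.total - self.unclassified

    @property
    def viral(self) -> int:
        return self._label_total(VIRAL_LABELS)

    @property
    def phage(self) -> int:
        """Bacterial viruses, inoviruses included."""
        return self._label_total(PHAGE_LABELS)

    @property
    def euk_virus(self) -> int:
        return self._label_total({Label.EUK_VIRUS})

    def percentages(self) -> dict[str, float]:
        """Printed-style integer percentages (half-away-from-zero)."""
        total, classified = self.total, self.classified
        return {
            "pct_classified": round_half_away(100 * classified / total),
            "pct_unclassified": round_half_away(100 * self.unclassified / total),
            "pct_phage_of_classified": round_half_away(100 * self.phage / classified)
            if classified else 0.0,
            "pct_euk_virus_of_classified": round_half_away(100 * self.euk_virus / classified)
            if classified else 0.0,
            "pct_viral_overall": round_half_away(100 * self.viral / total),
        }


def tally(
    records: Sequence[ClassificationRecord] = (),
    stage_counts_override: Mapping[tuple[PassId, Stage, Label], int] | None = None,
) -> StageTally:
    """Tally classifications, or rebuild the accounting from a printed-count
    override map (fixture mode)."""
    if stage_counts_override is not None:
        return StageTally(counts=dict(stage_counts_override))
    if not records:
        raise ValueError("records empty and no override map given")
    counter: Counter[tuple[PassId, Stage, Label]] = Counter()
    for rec in records:
        counter[(rec.pass_id, rec.stage, rec.label)] += 1
    return StageTally(counts=dict(counter))
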