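"""Linked virome + microbiome toy communities with planted ground truth.

The generator emulates the *structure* of a paired faecal sequencing design:
one virome (VP) assembly per community with phage / inovirus / eukaryotic
virus / bacterial / plasmid / unclassified contigs, and one microbiome (P)
assembly in which a small fraction of contigs is viral (prophages and
replicating phages), some of them active (producing virions, hence covered
by virome reads) and the rest dormant.  ARGs are planted on bacterial and
plasmid sequence at a configurable per-Mb rate and (optionally) on dormant
prophages.  Evidence tables emulate external-tool verdicts consistent with
the planted truth, corrupted at configurable noise rates; the decision logic
downstream — not the external tools — is what gets tested.

Everything is deterministic given the seed; the truth manifest records every
planted attribute and is the oracle for recovery tests.  Sequences are random
DNA built from start-to-stop codon cassettes so the ORF caller always finds
at least five genes per contig; circular contigs carry an exact 20-nt
terminal repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    Compartment,
    ContigRecord,
    CountTable,
    EvidenceRecord,
    EvidenceSource,
    SubjectType,
)

__all__ = [
    "CommunitySpec",
    "Community",
    "generate_community",
    "simulate_counts",
    "emulate_evidence",
    "write_community",
]

_LABELS = ["PHAGE", "INOVIRUS", "EUK_VIRUS", "BACTERIAL", "PLASMID", "UNCLASSIFIED"]
_CONTAMINATION_LABELS = {"BACTERIAL", "PLASMID"}

#: abundance bands (planted total RPKM across samples); the high band sits
#: well above the 100-RPKM pass split, the low band well below, so that the
#: split survives multinomial read sampling.
_HIGH_BAND = (250.0, 1200.0)
_LOW_BAND = (2.0, 50.0)
_CONTAM_FLOOR = 300.0  # virome bacterial/plasmid contigs are well covered
_CONTAM_CAP = 1200.0
_SPILL_BAND = (0.02, 0.3)  # virome reads cross-mapping onto dormant/bulk P contigs

_CONFIRMED_ARGS = [
    ("tet(W)", "tetracycline"),
    ("tet(40)", "tetracycline"),
    ("APH3'", "aminoglycoside"),
    ("ANT9", "aminoglycoside"),
    ("TEM", "beta-lactam"),
    ("ermB", "macrolide"),
    ("aadE", "aminoglycoside"),
    ("MexH", "multidrug"),
]
_TRANSPORTER_ARGS = [
    ("ABC_efflux", "efflux"),
    ("RND_efflux", "efflux"),
    ("tet_MFS_efflux", "efflux"),
]


@dataclass
class CommunitySpec:
    """Planted study conditions of one synthetic community.

    Defaults mirror the pig faecal study this pipeline models: 14 paired
    samples, 7.7 % of microbiome contigs viral, 23.7 % of those active,
    0.18 confirmed ARGs per bacterial Mb and none on phages.
    """

    seed: int = 0
    n_samples: int = 14
    n_virome_contigs: int = 120
    n_microbiome_contigs: int = 200
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "PHAGE": 0.58,
            "INOVIRUS": 0.06,
            "EUK_VIRUS": 0.12,
            "BACTERIAL": 0.04,
            "PLASMID": 0.02,
            "UNCLASSIFIED": 0.18,
        }
    )
    viral_p_fraction: float = 0.077
    active_fraction: float = 0.237
    arg_rate_bacterial: float = 0.18  # confirmed ARGs per bacterial Mb
    arg_rate_viral: float = 0.0  # ARGs per viral Mb (planted on dormant prophages)
    contamination_fraction: float = 0.08  # bacterial read share of the virome
    depth: int = 200_000  # mapped reads per sample
    length_range: tuple[int, int] = (2500, 30000)
    evidence_noise: tuple[float, float] = (0.0, 0.0)  # (false neg, false pos) per row
    duplicate_fraction: float = 0.10  # planted near-duplicates (dereplication)
    cross_overlap_fraction: float = 0.25  # viral-P contigs with a VP homolog
    high_abundance_fraction: float = 0.6  # of virome viral contigs

    def validate(self) -> None:
        fracs = {
            "viral_p_fraction": self.viral_p_fraction,
            "active_fraction": self.active_fraction,
            "contamination_fraction": self.contamination_fraction,
            "duplicate_fraction": self.duplicate_fraction,
            "cross_overlap_fraction": self.cross_overlap_fraction,
            "high_abundance_fraction": self.high_abundance_fraction,
            "false_negative_rate": self.evidence_noise[0],
            "false_positive_rate": self.evidence_noise[1],
        }
        for name, f in fracs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if set(self.class_proportions) - set(_LABELS):
            raise ValueError(f"unknown class labels {set(self.class_proportions) - set(_LABELS)}")
        if self.active_fraction > 0 and self.viral_p_fraction == 0:
            raise ValueError("active_fraction > 0 requires viral_p_fraction > 0")
        if self.n_samples < 1 or self.depth < 0:
            raise ValueError("need n_samples >= 1 and depth >= 0")
        lo, hi = self.length_range
        if not (2000 < lo <= hi):
            raise ValueError("length_range must satisfy 2000 < lo <= hi")
        if self.arg_rate_bacterial < 0 or self.arg_rate_viral < 0:
            raise ValueError("ARG rates must be non-negative")


@dataclass
class Community:
    spec: CommunitySpec
    contigs: list[ContigRecord]
    info: list[dict]  # one dict per contig, all planted attributes
    pairwise_virome: list[tuple[str, str, float, float]]
    cross_homology: list[tuple[str, str, float, float]]

    @property
    def truth(self) -> pd.DataFrame:
        """Truth manifest: one row per contig, every planted attribute."""
        rows = []
        for d in self.info:
            rows.append(
                {
                    "contig_id": d["contig_id"],
                    "compartment": d["compartment"],
                    "label": d["label"],
                    "expected_label": d["expected_label"],
                    "expected_stage": d["expected_stage"],
                    "clade": d["clade"],
                    "length_nt": d["length"],
                    "circular": d["circular"],
                    "abundance_tier": d["tier"],
                    "planted_total_rpkm": round(d["T_virome"], 4),
                    "planted_microbiome_rpkm": round(d["T_micro"], 4),
                    "n_orfs": d["n_orfs"],
                    "is_viral_p": d["is_viral_p"],
                    "active": d["active"],
                    "criteria": ";".join(sorted(d["criteria"])),
                    "arg_names": ";".join(a["name"] for a in d["args"]),
                    "arg_gene_indices": ";".join(str(a["gene_index"]) for a in d["args"]),
                    "arg_confirmed": ";".join(str(a["confirmed"]) for a in d["args"]),
                    "representative": d["representative"],
                    "cross_vp": d["cross_vp"],
                }
            )
        return pd.DataFrame(rows)

    def by_compartment(self, compartment: Compartment) -> list[ContigRecord]:
        return [c for c in self.contigs if c.compartment is compartment]

    def orf_counts(self) -> dict[str, int]:
        return {d["contig_id"]: d["n_orfs"] for d in self.info}

    def clades(self) -> dict[str, str]:
        return {d["contig_id"]: d["clade"] for d in self.info}


# ---------------------------------------------------------------------------
# sequence construction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_SET = {"TAA", "TAG", "TGA"}
_CODONS61 = np.array(
    ["".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in _STOP_SET]
)
_STOPS3 = np.array(sorted(_STOP_SET))


def _orf_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """Random DNA laid out as ATG...stop cassettes of 156-309 nt."""
    parts: list[str] = []
    total = 0
    while total < length:
        k = int(rng.integers(50, 101))
        body = "".join(_CODONS61[rng.integers(0, 61, size=k)])
        stop = str(_STOPS3[rng.integers(0, 3)])
        cassette = "ATG" + body + stop
        parts.append(cassette)
        total += len(cassette)
    return "".join(parts)[:length]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    arr[mask] = _BASES[rng.integers(0, 4, size=int(mask.sum()))]
    return arr.tobytes().decode()


def _circularize(seq: str, k: int = 20) -> str:
    return seq[: len(seq) - k] + seq[:k]


def _count_orfs(seq: str) -> int:
    from .io import ContigRecord, call_orfs

    rec = ContigRecord("tmp", "", Compartment.VIROME, len(seq), sequence=seq)
    return call_orfs(rec).n_orfs


# ---------------------------------------------------------------------------
# generation


def _plant_args(
    rng: np.random.Generator,
    length: int,
    n_orfs: int,
    confirmed_rate: float,
    transporter_rate: float,
) -> list[dict]:
    mb = length / 1e6
    n_conf = int(rng.poisson(confirmed_rate * mb))
    n_trans = int(rng.poisson(transporter_rate * mb))
    n_total = min(n_conf + n_trans, n_orfs)
    if n_total == 0:
        return []
    gene_idx = rng.choice(n_orfs, size=n_total, replace=False)
    out = []
    for j, gi in enumerate(gene_idx):
        confirmed = j < min(n_conf, n_total)
        pool = _CONFIRMED_ARGS if confirmed else _TRANSPORTER_ARGS
        name, drug = pool[int(rng.integers(0, len(pool)))]
        out.append(
            {"gene_index": int(gi), "name": name, "drug_class": drug, "confirmed": confirmed}
        )
    return out


def _new_info(contig_id: str, compartment: str) -> dict:
    return {
        "contig_id": contig_id,
        "compartment": compartment,
        "label": "UNCLASSIFIED",
        "expected_label": "UNCLASSIFIED",
        "expected_stage": "NONE",
        "stage_variant": "",
        "clade": "Unclassified",
        "length": 0,
        "circular": False,
        "tier": "",
        "T_virome": 0.0,
        "T_micro": 0.0,
        "n_orfs": 0,
        "sequence": None,
        "is_viral_p": False,
        "active": False,
        "criteria": set(),
        "args": [],
        "representative": "",
        "cross_vp": "",
    }


def generate_community(spec: CommunitySpec, with_sequences: bool = True) -> Community:
    """Build the contig sets and ground truth (deterministic given seed).

    With ``with_sequences=False`` only lengths, planted ORF counts and
    annotations are generated — enough for abundance/evidence simulation at
    large assembled sizes without building megabases of sequence text.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    labels = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[k] for k in labels], dtype=float)
    lo, hi = spec.length_range

    info: list[dict] = []
    pairwise: list[tuple[str, str, float, float]] = []
    cross: list[tuple[str, str, float, float]] = []

    # ---- virome (VP) contigs -------------------------------------------
    vp_originals: list[int] = []  # indices of non-duplicate VP contigs
    for i in range(spec.n_virome_contigs):
        d = _new_info(f"VP_C{i:05d}", "VIROME")
        parent: dict | None = None
        if vp_originals and rng.random() < spec.duplicate_fraction:
            parent = info[int(rng.choice(vp_originals))]
        if parent is not None:
            d["label"] = parent["label"]
            d["clade"] = parent["clade"]
            d["length"] = max(lo, int(parent["length"] * rng.uniform(0.85, 0.95)))
            if with_sequences:
                seq = _mutate(parent["sequence"][: d["length"]], 0.02, rng)
                d["sequence"] = seq
            d["representative"] = parent["contig_id"]
            ident = 0.98
            pairwise.append((d["contig_id"], parent["contig_id"], ident, 1.0))
        else:
            d["label"] = str(rng.choice(labels, p=probs))
            d["length"] = int(rng.integers(lo, hi + 1))
            if with_sequences:
                d["sequence"] = _orf_rich_sequence(rng, d["length"])
            d["representative"] = d["contig_id"]
            vp_originals.append(i)

        lab = d["label"]
        d["clade"] = d["clade"] if parent is not None else {
            "PHAGE": str(rng.choice(["Petitvirales", "Caudovirales"], p=[0.55, 0.45])),
            "INOVIRUS": "Tubulavirales",
            "EUK_VIRUS": "non-bacterial viruses",
            "BACTERIAL": "Bacteria",
            "PLASMID": "Plasmids",
            "UNCLASSIFIED": "Unclassified",
        }[lab]

        circ_p = {"INOVIRUS": 0.8, "PLASMID": 0.9}.get(lab, 0.05)
        if parent is None and rng.random() < circ_p:
            d["circular"] = True
            if with_sequences:
                d["sequence"] = _circularize(d["sequence"])

        if with_sequences:
            d["n_orfs"] = _count_orfs(d["sequence"])
        else:
            d["n_orfs"] = max(5, d["length"] // 300)

        # abundance tier and planted total virome RPKM
        if lab in _CONTAMINATION_LABELS:
            d["tier"] = "high"  # assembled from virome reads, hence well covered
            d["T_virome"] = math.nan  # filled from the contamination budget below
        else:
            high = rng.random() < spec.high_abundance_fraction
            d["tier"] = "high" if high else "low"
            band = _HIGH_BAND if high else _LOW_BAND
            d["T_virome"] = float(rng.uniform(*band))

        # deciding evidence stage (low-abundance pass only sees the
        # fallback classifier and the inovirus detector)
        if lab == "INOVIRUS":
            d["expected_stage"] = "INOVIRUS"
        elif lab == "PHAGE":
            if parent is not None:
                d["expected_stage"] = "SORTER" if d["tier"] == "high" else "SECONDARY"
            elif d["tier"] == "high":
                d["expected_stage"] = str(
                    rng.choice(["SORTER", "HOMOLOGY_PHROG", "SECONDARY"], p=[0.35, 0.35, 0.30])
                )
                if d["expected_stage"] == "HOMOLOGY_PHROG":
                    d["stage_variant"] = str(
                        rng.choice(["phrog", "override", "nucl"], p=[0.4, 0.3, 0.3])
                    )
            else:
                d["expected_stage"] = "SECONDARY"
        elif lab == "EUK_VIRUS":
            if d["tier"] == "high" and parent is None:
                d["expected_stage"] = str(rng.choice(["HOMOLOGY_PHROG", "SECONDARY"], p=[0.6, 0.4]))
                d["stage_variant"] = "nucl" if d["expected_stage"] == "HOMOLOGY_PHROG" else ""
            else:
                d["expected_stage"] = "SECONDARY"
        elif lab in _CONTAMINATION_LABELS:
            d["expected_stage"] = "HOMOLOGY_PHROG"
            d["stage_variant"] = "nucl"
        d["expected_label"] = lab if d["expected_stage"] != "NONE" else "UNCLASSIFIED"

        # planted ARGs (virome bacterial/plasmid contamination can carry them)
        if lab in _CONTAMINATION_LABELS:
            d["args"] = _plant_args(
                rng, d["length"], d["n_orfs"], spec.arg_rate_bacterial, 0.25 * spec.arg_rate_bacterial
            )
        info.append(d)

    # ---- microbiome (P) contigs ----------------------------------------
    vp_viral_idx = [
        i for i, d in enumerate(info)
        if d["label"] in ("PHAGE", "INOVIRUS", "EUK_VIRUS") and d["representative"] == d["contig_id"]
    ]
    p_start = len(info)
    for j in range(spec.n_microbiome_contigs):
        d = _new_info(f"P_C{j:05d}", "MICROBIOME")
        is_viral = rng.random() < spec.viral_p_fraction
        if is_viral:
            d["is_viral_p"] = True
            d["label"] = "PHAGE"
            d["clade"] = "Caudovirales"
            d["active"] = bool(rng.random() < spec.active_fraction)
            homolog = bool(vp_viral_idx) and rng.random() < spec.cross_overlap_fraction
            if homolog:
                parent = info[int(rng.choice(vp_viral_idx))]
                d["length"] = max(lo, int(parent["length"] * rng.uniform(0.85, 0.95)))
                if with_sequences:
                    d["sequence"] = _mutate(parent["sequence"][: d["length"]], 0.03, rng)
                d["cross_vp"] = parent["contig_id"]
                cross.append((d["contig_id"], parent["contig_id"], 0.97, 1.0))
                d["criteria"].add("VP_HOMOLOG")
            for crit in ("SECONDARY_POSITIVE", "TAXON_VIRAL"):
                if rng.random() < 0.6:
                    d["criteria"].add(crit)
            if not d["criteria"]:
                d["criteria"].add("SECONDARY_POSITIVE")
        else:
            d["label"] = str(rng.choice(["BACTERIAL", "PLASMID"], p=[0.92, 0.08]))
            d["clade"] = "Bacteria" if d["label"] == "BACTERIAL" else "Plasmids"
        d["expected_label"] = d["label"]

        if d["sequence"] is None:
            d["length"] = d["length"] or int(rng.integers(lo, hi + 1))
            if with_sequences:
                d["sequence"] = _orf_rich_sequence(rng, d["length"])
        if d["label"] == "PLASMID" and rng.random() < 0.9:
            d["circular"] = True
            if with_sequences:
                d["sequence"] = _circularize(d["sequence"])
        if with_sequences:
            d["n_orfs"] = _count_orfs(d["sequence"])
        else:
            d["n_orfs"] = max(5, d["length"] // 300)

        # virome coverage: virion-producing phages are abundant in the
        # virome; everything else sees only cross-mapping spillover
        if d["active"]:
            d["T_virome"] = float(rng.uniform(*_HIGH_BAND))
            d["tier"] = "high"
        elif spec.contamination_fraction > 0:
            d["T_virome"] = float(rng.uniform(*_SPILL_BAND))
        d["T_micro"] = float(rng.uniform(20.0, 500.0))
        d["representative"] = d["contig_id"]

        if d["is_viral_p"]:
            if not d["active"] and spec.arg_rate_viral > 0:
                d["args"] = _plant_args(rng, d["length"], d["n_orfs"], spec.arg_rate_viral, 0.0)
        else:
            d["args"] = _plant_args(
                rng, d["length"], d["n_orfs"], spec.arg_rate_bacterial, 0.25 * spec.arg_rate_bacterial
            )
        info.append(d)

    # ---- contamination budget for virome bacterial/plasmid contigs ------
    viral_mass = sum(
        d["T_virome"] * d["length"]
        for d in info
        if not math.isnan(d["T_virome"]) and d["T_virome"] > 0
    )
    contam = [d for d in info[:p_start] if d["label"] in _CONTAMINATION_LABELS]
    cf = spec.contamination_fraction
    if contam:
        if cf == 0:
            for d in contam:
                d["T_virome"] = 0.0
                d["tier"] = "low"
                d["expected_stage"] = "NONE"
                d["stage_variant"] = ""
                d["expected_label"] = "UNCLASSIFIED"
        else:
            budget = cf / (1.0 - cf) * viral_mass
            floor_mass = sum(_CONTAM_FLOOR * d["length"] for d in contam)
            if floor_mass > budget:
                raise ValueError(
                    "contamination_fraction too small to cover the planted "
                    "bacterial/plasmid virome contigs at assembly-grade depth; "
                    "raise contamination_fraction or reduce their proportions"
                )
            u = rng.uniform(0.2, 1.0, size=len(contam))
            extra = budget - floor_mass
            for d, ui in zip(contam, u / u.sum()):
                d["T_virome"] = min(_CONTAM_FLOOR + extra * ui / d["length"], _CONTAM_CAP)

    contigs = [
        ContigRecord(
            contig_id=d["contig_id"],
            sample_id="",
            compartment=Compartment(d["compartment"]),
            length_nt=d["length"],
            circular=d["circular"],
            sequence=d["sequence"],
        )
        for d in info
    ]
    return Community(
        spec=spec, contigs=contigs, info=info, pairwise_virome=pairwise, cross_homology=cross
    )


# ---------------------------------------------------------------------------
# read simulation


def _sample_ids(spec: CommunitySpec) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(spec.n_samples)]


def _allocate(
    rng: np.random.Generator,
    spec: CommunitySpec,
    members: list[dict],
    t_key: str,
) -> CountTable:
    """Multinomial read allocation with an explicit unmapped-read sink.

    Per-contig probability mass is T*L/1e9 split over samples with a mild
    lognormal sample-to-sample jitter, so the expected total RPKM of contig i
    equals its planted target T_i regardless of depth or sample count.
    """
    samples = _sample_ids(spec)
    counts: dict[tuple[str, str], int] = {}
    totals = {s: max(spec.depth, 1) for s in samples}
    if spec.depth == 0 or not members:
        return CountTable(counts={}, sample_totals=totals)
    t = np.array([d[t_key] for d in members], dtype=float)
    L = np.array([d["length"] for d in members], dtype=float)
    jitter = rng.lognormal(mean=0.0, sigma=0.25, size=(len(members), spec.n_samples))
    g = jitter / jitter.sum(axis=1, keepdims=True)
    p = (t * L)[:, None] * g / 1e9  # (contig, sample) probability of one read
    col = p.sum(axis=0)
    if (col > 0.98).any():
        raise ValueError(
            "planted abundances exceed the per-sample read budget; "
            "reduce contig counts or planted RPKM"
        )
    for s_idx, sid in enumerate(samples):
        vec = np.append(p[:, s_idx], 1.0 - col[s_idx])
        draw = rng.multinomial(spec.depth, vec)
        for c_idx in np.flatnonzero(draw[:-1]):
            counts[(members[c_idx]["contig_id"], sid)] = int(draw[c_idx])
    return CountTable(counts=counts, sample_totals=totals)


def simulate_counts(community: Community, spec: CommunitySpec | None = None) -> tuple[CountTable, CountTable]:
    """Simulate the two read mappings (virome reads, microbiome reads).

    Virome reads map onto both contig sets (that cross-mapping is what the
    activity partition consumes); microbiome reads map onto the microbiome
    contigs.  Deterministic given the community seed.
    """
    spec = spec or community.spec
    rng = np.random.default_rng([spec.seed % (2**31), 13])
    virome_members = [d for d in community.info if d["T_virome"] > 0]
    virome = _allocate(rng, spec, virome_members, "T_virome")
    micro_members = [
        d for d in community.info if d["compartment"] == "MICROBIOME" and d["T_micro"] > 0
    ]
    microbiome = _allocate(rng, spec, micro_members, "T_micro")
    return virome, microbiome


# ---------------------------------------------------------------------------
# evidence emulation


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def _virome_rows(d: dict, rng: np.random.Generator) -> list[EvidenceRecord]:
    cid = d["contig_id"]
    stage = d["expected_stage"]
    rows: list[EvidenceRecord] = []
    if stage == "SORTER":
        cat = str(rng.choice(["cat1", "cat2", "cat3"], p=[0.55, 0.40, 0.05]))
        rows.append(EvidenceRecord(cid, EvidenceSource.SORTER, cat, SubjectType.PHAGE))
    elif stage == "INOVIRUS":
        cat = str(rng.choice(["confirmed", "putative"]))
        rows.append(EvidenceRecord(cid, EvidenceSource.INOVIRUS, cat, SubjectType.PHAGE))
    elif stage == "SECONDARY":
        if d["label"] == "EUK_VIRUS":
            rows.append(EvidenceRecord(cid, EvidenceSource.SECONDARY, "virus", SubjectType.EUK_VIRUS))
        else:
            rows.append(EvidenceRecord(cid, EvidenceSource.SECONDARY, "phage", SubjectType.PHAGE))
    elif stage == "HOMOLOGY_PHROG":
        variant = d["stage_variant"]
        subject = {
            "PHAGE": SubjectType.PHAGE,
            "EUK_VIRUS": SubjectType.EUK_VIRUS,
            "BACTERIAL": SubjectType.BACTERIAL,
            "PLASMID": SubjectType.PLASMID,
        }[d["label"]]
        if variant == "nucl":
            rows.append(
                EvidenceRecord(
                    cid, EvidenceSource.NUCL_HOMOLOGY, f"nt:{d['clade']}", subject,
                    e_value=_loguniform(rng, -40, -17),
                )
            )
        else:  # 'phrog' or 'override': phage-like proteins carry the call
            if variant == "override":
                rows.append(
                    EvidenceRecord(
                        cid, EvidenceSource.NUCL_HOMOLOGY, "nt:host_genome", SubjectType.BACTERIAL,
                        e_value=_loguniform(rng, -40, -17),
                    )
                )
            n_hits = max(int(math.ceil(0.40 * d["n_orfs"])), 2)
            genes = rng.choice(d["n_orfs"], size=min(n_hits, d["n_orfs"]), replace=False)
            for gi in sorted(int(g) for g in genes):
                rows.append(
                    EvidenceRecord(
                        cid, EvidenceSource.PROT_PROFILE, f"phrog_{int(rng.integers(1, 30000))}",
                        SubjectType.PHAGE, e_value=_loguniform(rng, -30, -13), gene_index=gi,
                    )
                )
    return rows


def _microbiome_rows(d: dict, rng: np.random.Generator) -> list[EvidenceRecord]:
    cid = d["contig_id"]
    rows: list[EvidenceRecord] = []
    if d["is_viral_p"]:
        if "SECONDARY_POSITIVE" in d["criteria"]:
            rows.append(EvidenceRecord(cid, EvidenceSource.SECONDARY, "phage", SubjectType.PHAGE))
        if "TAXON_VIRAL" in d["criteria"]:
            rows.append(EvidenceRecord(cid, EvidenceSource.TAXON, "viral", SubjectType.PHAGE))
    else:
        if rng.random() < 0.7:
            taxon = str(rng.choice(["Firmicutes", "Bacteroidetes", "Proteobacteria"]))
            rows.append(EvidenceRecord(cid, EvidenceSource.TAXON, taxon, SubjectType.BACTERIAL))
    return rows


def _arg_rows(d: dict, rng: np.random.Generator) -> list[EvidenceRecord]:
    rows: list[EvidenceRecord] = []
    cid = d["contig_id"]
    for a in d["args"]:
        gi = a["gene_index"]
        rows.append(
            EvidenceRecord(
                cid, EvidenceSource.ARG_PROFILE, a["name"], SubjectType.NA,
                e_value=_loguniform(rng, -120, -40), gene_index=gi,
            )
        )
        if a["confirmed"]:
            rows.append(
                EvidenceRecord(
                    cid, EvidenceSource.ARG_HOMOLOGY, a["name"], SubjectType.NA,
                    e_value=_loguniform(rng, -80, -30), gene_index=gi,
                )
            )
            rows.append(
                EvidenceRecord(cid, EvidenceSource.ARG_CONFIRMED, a["name"], SubjectType.NA, gene_index=gi)
            )
    return rows


def emulate_evidence(
    community: Community, spec: CommunitySpec | None = None
) -> tuple[list[EvidenceRecord], list[EvidenceRecord]]:
    """Emit (virome, microbiome) evidence tables consistent with the truth.

    With zero noise the full pipeline recovers every planted attribute
    exactly.  Noise is applied per row, independently: false negatives drop
    rows, false positives add spurious sorter/taxon rows.
    """
    spec = spec or community.spec
    rng = np.random.default_rng([spec.seed % (2**31), 17])
    fn, fp = spec.evidence_noise
    virome_rows: list[EvidenceRecord] = []
    micro_rows: list[EvidenceRecord] = []
    for d in community.info:
        if d["compartment"] == "VIROME":
            virome_rows.extend(_virome_rows(d, rng))
            virome_rows.extend(_arg_rows(d, rng))
        else:
            micro_rows.extend(_microbiome_rows(d, rng))
            micro_rows.extend(_arg_rows(d, rng))
    if fn > 0:
        virome_rows = [r for r in virome_rows if rng.random() >= fn]
        micro_rows = [r for r in micro_rows if rng.random() >= fn]
    if fp > 0:
        for d in community.info:
            if rng.random() < fp:
                if d["compartment"] == "VIROME":
                    virome_rows.append(
                        EvidenceRecord(d["contig_id"], EvidenceSource.SORTER, "cat2", SubjectType.PHAGE)
                    )
                else:
                    micro_rows.append(
                        EvidenceRecord(d["contig_id"], EvidenceSource.TAXON, "viral", SubjectType.PHAGE)
                    )
    return virome_rows, micro_rows


# ---------------------------------------------------------------------------
# fixture output


def write_community(community: Community, outdir, spec: CommunitySpec | None = None) -> dict[str, str]:
    """Write the community in the exact formats the readers consume.

    Returns a name -> path mapping of everything written (FASTA per
    compartment, evidence/counts/totals TSVs, pairwise and cross-homology
    tables, and the truth manifest).
    """
    from pathlib import Path

    from .io import write_contigs, write_counts, write_evidence

    spec = spec or community.spec
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    vp = community.by_compartment(Compartment.VIROME)
    p = community.by_compartment(Compartment.MICROBIOME)
    if vp and vp[0].sequence is not None:
        write_contigs(vp, outdir / "vp_contigs.fasta")
        write_contigs(p, outdir / "p_contigs.fasta")
        paths["vp_fasta"] = str(outdir / "vp_contigs.fasta")
        paths["p_fasta"] = str(outdir / "p_contigs.fasta")

    ev_vp, ev_p = emulate_evidence(community, spec)
    write_evidence(ev_vp, outdir / "evidence_vp.tsv")
    write_evidence(ev_p, outdir / "evidence_p.tsv")
    paths["evidence_vp"] = str(outdir / "evidence_vp.tsv")
    paths["evidence_p"] = str(outdir / "evidence_p.tsv")

    vc, mc = simulate_counts(community, spec)
    write_counts(vc, outdir / "virome_counts.tsv", outdir / "virome_totals.tsv")
    write_counts(mc, outdir / "microbiome_counts.tsv", outdir / "microbiome_totals.tsv")
    paths.update(
        virome_counts=str(outdir / "virome_counts.tsv"),
        virome_totals=str(outdir / "virome_totals.tsv"),
        microbiome_counts=str(outdir / "microbiome_counts.tsv"),
        microbiome_totals=str(outdir / "microbiome_totals.tsv"),
    )

    with open(outdir / "pairwise_vp.tsv", "w") as fh:
        fh.write("contig_a\tcontig_b\tidentity\tcoverage\n")
        for a, b, i, c in community.pairwise_virome:
            fh.write(f"{a}\t{b}\t{i}\t{c}\n")
    with open(outdir / "cross_homology.tsv", "w") as fh:
        fh.write("p_contig\tvp_contig\tidentity\tcoverage\n")
        for a, b, i, c in community.cross_homology:
            fh.write(f"{a}\t{b}\t{i}\t{c}\n")
    community.truth.to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
    paths.update(
        pairwise_vp=str(outdir / "pairwise_vp.tsv"),
        cross_homology=str(outdir / "cross_homology.tsv"),
        truth_manifest=str(outdir / "truth_manifest.tsv"),
    )
    return paths
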