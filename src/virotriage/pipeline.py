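"""End-to-end orchestration: files in, reports out.

Two entry points: :func:`run_pipeline` drives the file-based run used by the
command line (contig filtering -> RPKM -> dereplication -> triage cascade ->
viral-P/activity -> ARG census -> reports, every output stamped with the
configuration hash), and :func:`run_synthetic` runs the same stages in
memory on a generated community and scores recovery against the planted
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._util import config_hash
from .abundance import AbundanceMatrix, ClusterAssignment, clade_matrix, compute_rpkm, dereplicate
from .activity import (
    ActivityRecord,
    ActivityStatus,
    OverlapReport,
    identify_viral_p,
    overlap_report,
    partition_activity,
)
from .arg_census import (
    ArgCrossTab,
    ArgHit,
    DensityReport,
    call_args,
    classify_arg_contigs,
    confirmed_hits,
    density_report,
    enrichment_ratio,
)
from .io import Compartment, ContigRecord, read_contigs, read_counts, read_table
from .synthetic import Community, CommunitySpec, emulate_evidence, generate_community, simulate_counts
from .triage import ClassificationRecord, StageTally, TriageConfig, VIRAL_LABELS, run_cascade, tally

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_synthetic", "read_pairs"]


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    vp_fasta: str
    p_fasta: str
    evidence_vp: str
    evidence_p: str
    virome_counts: str
    virome_totals: str
    microbiome_counts: str
    microbiome_totals: str
    pairwise_vp: str
    cross_homology: str
    outdir: str
    min_len: int = 2000
    rpkm_cut: float = 100.0
    e_nucl: float = 1e-16
    e_phrog: float = 1e-12
    phrog_min_orfs: int = 5
    phrog_fraction: float = 0.35
    id_cut: float = 0.95
    cov_cut: float = 0.80
    breadth_cut: float = 0.50
    rpkm_floor: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def input_paths(self) -> list[str]:
        return [
            self.vp_fasta, self.p_fasta, self.evidence_vp, self.evidence_p,
            self.virome_counts, self.virome_totals, self.microbiome_counts,
            self.microbiome_totals, self.pairwise_vp, self.cross_homology,
        ]

    def hash(self) -> str:
        return config_hash(dataclasses.asdict(self))


def read_pairs(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Read a pairwise identity table (two id columns, identity, coverage)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (id_a, id_b, identity, coverage)")
    return [
        (str(r.iloc[0]), str(r.iloc[1]), float(r.iloc[2]), float(r.iloc[3]))
        for _, r in df.iterrows()
    ]


@dataclass
class PipelineResult:
    vp_matrix: AbundanceMatrix
    clusters: ClusterAssignment
    classes: list[ClassificationRecord]
    tally: StageTally
    activity: list[ActivityRecord]
    overlap: OverlapReport
    arg_hits: list[ArgHit]
    crosstab: ArgCrossTab
    densities: dict[str, DensityReport]
    enrichment_fold: float | None = None
    recovery: dict = field(default_factory=dict)


def _census(
    vp_contigs: Sequence[ContigRecord],
    p_contigs: Sequence[ContigRecord],
    classes: Sequence[ClassificationRecord],
    activity: Sequence[ActivityRecord],
    arg_hits: Sequence[ArgHit],
    orf_counts: dict[str, int],
) -> tuple[ArgCrossTab, dict[str, DensityReport], float | None]:
    crosstab = classify_arg_contigs(arg_hits, classes, activity)
    viral_vp_ids = {r.contig_id for r in classes if r.label in VIRAL_LABELS}
    p_viral_ids = {r.contig_id for r in activity if r.is_viral_p}
    bact_ids = {c.contig_id for c in p_contigs} - p_viral_ids
    confirmed = confirmed_hits(arg_hits)

    def _mb(ids: set[str], pool: Sequence[ContigRecord]) -> float:
        return sum(c.length_nt for c in pool if c.contig_id in ids) / 1e6

    def _genes(ids: set[str]) -> int:
        return max(1, sum(orf_counts.get(cid, 0) for cid in ids))

    densities: dict[str, DensityReport] = {}
    if bact_ids:
        densities["microbiome_bacterial"] = density_report(
            [h for h in confirmed if h.contig_id in bact_ids],
            n_genes=_genes(bact_ids),
            assembled_mb=max(_mb(bact_ids, p_contigs), 1e-9),
            compartment="microbiome_bacterial",
            n_contigs=len(bact_ids),
        )
    if viral_vp_ids:
        densities["virome_viral"] = density_report(
            [h for h in confirmed if h.contig_id in viral_vp_ids],
            n_genes=_genes(viral_vp_ids),
            assembled_mb=max(_mb(viral_vp_ids, vp_contigs), 1e-9),
            compartment="virome_viral",
            n_contigs=len(viral_vp_ids),
        )
    enrich = None
    if "microbiome_bacterial" in densities and "virome_viral" in densities:
        enrich = enrichment_ratio(densities["microbiome_bacterial"], densities["virome_viral"])
    return crosstab, densities, enrich


def _core(
    vp_contigs: Sequence[ContigRecord],
    p_contigs: Sequence[ContigRecord],
    ev_vp,
    ev_p,
    virome_counts,
    micro_counts,
    pairwise_vp,
    cross_homology,
    orf_counts: dict[str, int],
    clades: dict[str, str] | None,
    triage_config: TriageConfig,
    breadth_cut: float,
    rpkm_floor: float,
) -> PipelineResult:
    all_contigs = list(vp_contigs) + list(p_contigs)
    full_matrix = compute_rpkm(virome_counts, all_contigs)
    vp_matrix = AbundanceMatrix(full_matrix.rpkm.loc[[c.contig_id for c in vp_contigs]])
    totals = vp_matrix.contig_total.to_dict()
    clusters = dereplicate(vp_contigs, pairwise_vp)
    classes = run_cascade(
        vp_contigs, ev_vp, totals, orf_counts=orf_counts, config=triage_config, clades=clades
    )
    stage_tally = tally(classes)
    viral_p = identify_viral_p(
        ev_p, cross_homology, contig_ids=[c.contig_id for c in p_contigs]
    )
    lengths = {c.contig_id: c.length_nt for c in all_contigs}
    activity = partition_activity(
        viral_p, virome_counts, lengths, breadth_cut=breadth_cut, rpkm_floor=rpkm_floor
    )
    overlap = overlap_report(classes, activity, cross_homology, vp_matrix)
    arg_hits = call_args(list(ev_vp) + list(ev_p))
    crosstab, densities, enrich = _census(
        vp_contigs, p_contigs, classes, activity, arg_hits, orf_counts
    )
    return PipelineResult(
        vp_matrix=vp_matrix,
        clusters=clusters,
        classes=classes,
        tally=stage_tally,
        activity=activity,
        overlap=overlap,
        arg_hits=arg_hits,
        crosstab=crosstab,
        densities=densities,
        enrichment_fold=enrich,
    )


def run_synthetic(spec: CommunitySpec, community: Community | None = None) -> PipelineResult:
    """Generate (or reuse) a community, run every stage, score recovery."""
    community = community or generate_community(spec)
    virome_counts, micro_counts = simulate_counts(community, spec)
    ev_vp, ev_p = emulate_evidence(community, spec)
    vp_contigs = community.by_compartment(Compartment.VIROME)
    p_contigs = community.by_compartment(Compartment.MICROBIOME)
    result = _core(
        vp_contigs, p_contigs, ev_vp, ev_p, virome_counts, micro_counts,
        community.pairwise_virome, community.cross_homology,
        community.orf_counts(), community.clades(),
        TriageConfig(), 0.50, 1.0,
    )
    result.recovery = score_recovery(community, result)
    return result


def score_recovery(community: Community, result: PipelineResult) -> dict:
    """Compare pipeline output against the planted truth manifest."""
    truth = {d["contig_id"]: d for d in community.info}
    classes = {r.contig_id: r for r in result.classes}
    n = len(classes)
    label_ok = sum(
        1 for cid, r in classes.items() if r.label.value == truth[cid]["expected_label"]
    )
    stage_ok = sum(
        1 for cid, r in classes.items() if r.stage.value == truth[cid]["expected_stage"]
    )
    act = {r.contig_id: r for r in result.activity}
    p_ids = [cid for cid, d in truth.items() if d["compartment"] == "MICROBIOME"]
    vp_ok = sum(1 for cid in p_ids if act[cid].is_viral_p == truth[cid]["is_viral_p"])
    viral_p_ids = [cid for cid in p_ids if truth[cid]["is_viral_p"]]
    act_ok = sum(
        1
        for cid in viral_p_ids
        if (act[cid].status is ActivityStatus.ACTIVE) == truth[cid]["active"]
    )
    planted_conf = {
        (cid, a["gene_index"])
        for cid, d in truth.items()
        for a in d["args"]
        if a["confirmed"]
    }
    found_conf = {
        (h.contig_id, h.gene_index) for h in confirmed_hits(result.arg_hits)
    }
    # cluster partition: representative maps must agree with the manifest
    rep_ok = sum(
        1
        for cid, r in result.clusters.representative.items()
        if r == truth[cid]["representative"]
    )
    return {
        "n_virome_contigs": n,
        "label_accuracy_pct": 100.0 * label_ok / n if n else 100.0,
        "stage_accuracy_pct": 100.0 * stage_ok / n if n else 100.0,
        "viral_p_accuracy_pct": 100.0 * vp_ok / len(p_ids) if p_ids else 100.0,
        "activity_accuracy_pct": 100.0 * act_ok / len(viral_p_ids) if viral_p_ids else 100.0,
        "arg_recovery_exact": planted_conf == found_conf,
        "n_planted_confirmed_args": len(planted_conf),
        "n_recovered_confirmed_args": len(found_conf),
        "cluster_accuracy_pct": 100.0 * rep_ok / len(result.clusters.representative)
        if result.clusters.representative
        else 100.0,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based run; deterministic and idempotent on identical inputs."""
    missing = [p for p in config.input_paths() if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    vp_contigs = read_contigs(config.vp_fasta, Compartment.VIROME, config.min_len)
    p_contigs = read_contigs(config.p_fasta, Compartment.MICROBIOME, config.min_len)
    ev_vp = read_table(config.evidence_vp, "evidence")
    ev_p = read_table(config.evidence_p, "evidence")
    virome_counts = read_counts(config.virome_counts, config.virome_totals)
    micro_counts = read_counts(config.microbiome_counts, config.microbiome_totals)
    pairwise_vp = read_pairs(config.pairwise_vp)
    cross = read_pairs(config.cross_homology)
    known = {c.contig_id for c in vp_contigs} | {c.contig_id for c in p_contigs}
    virome_counts.counts = {
        k: v for k, v in virome_counts.counts.items() if k[0] in known
    }
    micro_counts.counts = {k: v for k, v in micro_counts.counts.items() if k[0] in known}

    from .io import call_orfs

    orf_counts = {c.contig_id: call_orfs(c).n_orfs for c in vp_contigs + p_contigs}
    triage_config = TriageConfig(
        rpkm_cut=config.rpkm_cut,
        e_nucl=config.e_nucl,
        e_phrog=config.e_phrog,
        phrog_min_orfs=config.phrog_min_orfs,
        phrog_fraction=config.phrog_fraction,
    )
    result = _core(
        vp_contigs, p_contigs, ev_vp, ev_p, virome_counts, micro_counts,
        pairwise_vp, cross, orf_counts, None, triage_config,
        config.breadth_cut, config.rpkm_floor,
    )
    _write_outputs(result, outdir, config.hash())
    return result


def _write_outputs(result: PipelineResult, outdir: Path, cfg_hash: str) -> None:
    stamp = f"# config_hash={cfg_hash}\n"

    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write(stamp + "contig_id\tlabel\tstage\tpass_id\tclade\n")
        for r in result.classes:
            fh.write(
                f"{r.contig_id}\t{r.label.value}\t{r.stage.value}\t{r.pass_id.value}\t{r.clade or ''}\n"
            )

    with open(outdir / "tally.tsv", "w") as fh:
        fh.write(stamp + "pass_id\tstage\tlabel\tcontigs\n")
        for (pid, stg, lab), nn in sorted(
            result.tally.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value)
        ):
            fh.write(f"{pid.value}\t{stg.value}\t{lab.value}\t{nn}\n")
        for k, v in result.tally.percentages().items():
            fh.write(f"# {k}={v:g}\n")

    with open(outdir / "abundance_matrix.tsv", "w") as fh:
        fh.write(stamp)
        result.vp_matrix.rpkm.round(6).to_csv(fh, sep="\t", index_label="contig_id")

    grouped, shares = clade_matrix(result.vp_matrix, result.classes)
    with open(outdir / "clade_matrix.tsv", "w") as fh:
        fh.write(stamp)
        out = grouped.round(4).copy()
        out["pct_total_rpkm"] = shares.round(2)
        out.to_csv(fh, sep="\t", index_label="clade")

    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write(stamp + "contig_id\trepresentative\n")
        for cid, rep in sorted(result.clusters.representative.items()):
            fh.write(f"{cid}\t{rep}\n")

    with open(outdir / "activity.tsv", "w") as fh:
        fh.write(stamp + "contig_id\tis_viral_p\tcriteria\tbreadth\tvirome_rpkm\tstatus\n")
        for r in result.activity:
            crit = ";".join(sorted(c.value for c in r.criteria_hit))
            fh.write(
                f"{r.contig_id}\t{int(r.is_viral_p)}\t{crit}\t{r.breadth:.4f}"
                f"\t{r.virome_rpkm:.4f}\t{r.status.value}\n"
            )

    ov = result.overlap
    with open(outdir / "overlap.tsv", "w") as fh:
        fh.write(stamp + "subset\tcontigs\tpct_virome_rpkm\n")
        fh.write(f"shared\t{ov.shared}\t{ov.active_rpkm_share.get('shared', 0):.2f}\n")
        fh.write(f"virome_only\t{ov.virome_only}\t{ov.active_rpkm_share.get('virome_only', 0):.2f}\n")
        fh.write(
            f"microbiome_only_active\t{ov.microbiome_only_active}"
            f"\t{ov.active_rpkm_share.get('microbiome_only_active', 0):.2f}\n"
        )
        fh.write(f"microbiome_only_dormant\t{ov.microbiome_only_dormant}\t0.00\n")

    with open(outdir / "arg_hits.tsv", "w") as fh:
        fh.write(stamp + "contig_id\tgene_index\targ_name\tdrug_class\ttiers\te_value\tlow_confidence\n")
        for h in result.arg_hits:
            tiers = ";".join(sorted(t.value for t in h.tiers))
            e = "NA" if h.e_value is None else repr(h.e_value)
            fh.write(
                f"{h.contig_id}\t{h.gene_index}\t{h.arg_name}\t{h.drug_class}"
                f"\t{tiers}\t{e}\t{int(h.low_confidence)}\n"
            )

    with open(outdir / "density.tsv", "w") as fh:
        fh.write(
            stamp
            + "compartment\tn_args\tn_genes\tassembled_mb\tper_gene\tper_mb"
            + "\tper_bacterial_genome\tper_phage_genome_bound\tdetection_limit_per_mb"
            + "\tdetection_limit_fraction_pct\tis_upper_bound\n"
        )
        for rep in result.densities.values():
            fh.write(
                f"{rep.compartment}\t{rep.n_args}\t{rep.n_genes}\t{rep.assembled_mb:.4f}"
                f"\t{rep.per_gene:.3e}\t{rep.per_mb:.4f}\t{rep.per_bacterial_genome:.4f}"
                f"\t{'' if rep.per_phage_genome_bound is None else f'{rep.per_phage_genome_bound:.3e}'}"
                f"\t{'' if rep.detection_limit_per_mb is None else f'{rep.detection_limit_per_mb:.4f}'}"
                f"\t{'' if rep.detection_limit_fraction is None else f'{rep.detection_limit_fraction:.4f}'}"
                f"\t{int(rep.is_upper_bound)}\n"
            )
        if result.enrichment_fold is not None:
            fh.write(f"# bacterial_vs_phage_enrichment_fold={result.enrichment_fold:.1f}\n")
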