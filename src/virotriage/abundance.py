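"""RPKM abundance matrices, species-level dereplication and clade grouping.

RPKM (reads per kilobase of contig per million mapped reads) is the abundance
unit throughout: ``rpkm = r / ((L/1000) * (M/1e6))`` with r the mapped reads
of a contig in a sample, L the contig length and M the sample's total mapped
reads.  Dereplication clusters contigs at the species level (>95 % nucleotide
identity over >=80 % of the shorter contig) by greedy centroid clustering on
a precomputed pairwise-identity table; the package does not align genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ContigRecord, CountTable
from .triage import ClassificationRecord, Label

__all__ = [
    "AbundanceMatrix",
    "ClusterAssignment",
    "compute_rpkm",
    "dereplicate",
    "clade_matrix",
    "compare_groups",
    "CLADE_ROWS",
]

#: Row order of the grouped abundance matrix.
CLADE_ROWS = [
    "Tubulavirales",
    "Petitvirales",
    "non-bacterial viruses",
    "Caudovirales",
    "Bacteria",
    "Plasmids",
    "Unclassified",
]

#: Default clade for labels that carry no explicit clade annotation.
DEFAULT_CLADE = {
    Label.PHAGE: "Caudovirales",
    Label.INOVIRUS: "Tubulavirales",
    Label.EUK_VIRUS: "non-bacterial viruses",
    Label.BACTERIAL: "Bacteria",
    Label.PLASMID: "Plasmids",
    Label.UNCLASSIFIED: "Unclassified",
}


@dataclass
class AbundanceMatrix:
    """Contigs x samples RPKM matrix with per-contig totals."""

    rpkm: pd.DataFrame  # index contig_id, columns sample_id

    @property
    def contig_total(self) -> pd.Series:
        return self.rpkm.sum(axis=1)

    def total(self) -> float:
        return float(self.rpkm.to_numpy().sum())


@dataclass
class ClusterAssignment:
    representative: dict[str, str]  # contig -> representative
    clusters: dict[str, list[str]]  # representative -> members (incl. itself)

    def n_clusters(self) -> int:
        return len(self.clusters)


def compute_rpkm(counts: CountTable, contigs: Sequence[ContigRecord]) -> AbundanceMatrix:
    """RPKM for every (contig, sample); missing pairs are 0."""
    lengths = {c.contig_id: c.length_nt for c in contigs}
    unknown = {cid for (cid, _s) in counts.counts} - set(lengths)
    if unknown:
        raise ValueError(f"counts reference unknown contig_id(s): {sorted(unknown)[:5]}")
    for sid, m in counts.sample_totals.items():
        if m <= 0:
            raise ValueError(f"sample {sid}: total mapped reads must be positive")
    samples = counts.samples
    index = [c.contig_id for c in contigs]
    mat = pd.DataFrame(0.0, index=index, columns=samples)
    for (cid, sid), r in counts.counts.items():
        if sid not in counts.sample_totals:
            raise ValueError(f"sample {sid} missing from sample_totals")
        L = lengths[cid]
        M = counts.sample_totals[sid]
        mat.at[cid, sid] = r / ((L / 1000.0) * (M / 1e6))
    return AbundanceMatrix(rpkm=mat)


def dereplicate(
    contigs: Sequence[ContigRecord],
    pairwise: Iterable[tuple[str, str, float, float]],
    id_cut: float = 0.95,
    cov_cut: float = 0.80,
) -> ClusterAssignment:
    """Greedy centroid clustering at species-level identity.

    Contigs are visited longest-first (ties by lexicographic id); each joins
    the first existing representative it matches with identity strictly above
    ``id_cut`` and aligned coverage of the shorter contig >= ``cov_cut``,
    otherwise it founds its own cluster.  ``pairwise`` is undirected; when a
    pair occurs twice the best identity/coverage is kept.  The result is
    independent of the input pair ordering.
    """
    known = {c.contig_id for c in contigs}
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, ident, cov in pairwise:
        if a not in known or b not in known:
            raise ValueError(f"pairwise row references unknown contig: {a!r}/{b!r}")
        if not (0 <= ident <= 1 and 0 <= cov <= 1):
            raise ValueError("identity and coverage must lie in [0, 1]")
        key = (a, b) if a <= b else (b, a)
        old = edges.get(key)
        if old is None or (ident, cov) > old:
            edges[key] = (ident, cov)

    order = sorted(contigs, key=lambda c: (-c.length_nt, c.contig_id))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    clusters: dict[str, list[str]] = {}
    for c in order:
        cid = c.contig_id
        home = None
        for rep in reps:
            key = (cid, rep) if cid <= rep else (rep, cid)
            edge = edges.get(key)
            if edge is not None and edge[0] > id_cut and edge[1] >= cov_cut:
                home = rep
                break
        if home is None:
            reps.append(cid)
            assignment[cid] = cid
            clusters[cid] = [cid]
        else:
            assignment[cid] = home
            clusters[home].append(cid)
    return ClusterAssignment(representative=assignment, clusters=clusters)


def clade_matrix(
    matrix: AbundanceMatrix,
    classes: Sequence[ClassificationRecord],
    clades: Mapping[str, str] | None = None,
    top_cut: float = 100.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Group the abundance matrix by clade over the high-abundance subset.

    Only contigs with total RPKM strictly above ``top_cut`` are kept.  Rows
    follow :data:`CLADE_ROWS` (rows for absent clades are dropped, unlisted
    clades appended).  Returns the grouped matrix and each clade's share of
    total RPKM in percent (summing to 100 over a non-empty selection).
    """
    clades = clades or {}
    by_id = {r.contig_id: r for r in classes}
    totals = matrix.contig_total
    selected = [cid for cid in matrix.rpkm.index if totals[cid] > top_cut]
    missing = [cid for cid in selected if cid not in by_id]
    if missing:
        raise ValueError(f"selected contigs missing classification: {missing[:5]}")

    def clade_of(cid: str) -> str:
        rec = by_id[cid]
        if rec.clade:
            return rec.clade
        return clades.get(cid) or DEFAULT_CLADE[rec.label]

    sub = matrix.rpkm.loc[selected]
    groups = pd.Series([clade_of(cid) for cid in selected], index=sub.index, dtype=object)
    grouped = sub.groupby(groups).sum() if selected else pd.DataFrame(columns=matrix.rpkm.columns)
    order = [c for c in CLADE_ROWS if c in grouped.index]
    order += [c for c in grouped.index if c not in order]
    grouped = grouped.loc[order]
    grand = float(grouped.to_numpy().sum()) if selected else 0.0
    if grand > 0:
        shares = grouped.sum(axis=1) / grand * 100.0
    else:
        shares = pd.Series(0.0, index=grouped.index)
    return grouped, shares


def compare_groups(
    grouped: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    clade: str,
) -> tuple[float, float]:
    """Welch two-sample t-test on per-sample RPKM of one clade row.

    Used e.g. to ask whether piglet samples carry more Caudovirales than
    adult samples.  Returns (statistic, p-value).
    """
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ValueError("sample groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if clade not in grouped.index:
        raise ValueError(f"clade {clade!r} not in matrix")
    xa = grouped.loc[clade, a].to_numpy(dtype=float)
    xb = grouped.loc[clade, b].to_numpy(dtype=float)
    res = stats.ttest_ind(xa, xb, equal_var=False)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups, identical means
        p = 1.0
        stat = 0.0
    return stat, p
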