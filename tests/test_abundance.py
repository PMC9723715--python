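"""RPKM arithmetic, greedy dereplication and the clade-grouped matrix."""

import numpy as np
import pytest
from scipy import stats

from virotriage import (
    ClassificationRecord,
    Compartment,
    ContigRecord,
    CountTable,
    Label,
    PassId,
    Stage,
    clade_matrix,
    compare_groups,
    compute_rpkm,
    dereplicate,
)


def contig(cid, length=2000):
    return ContigRecord(cid, "", Compartment.VIROME, length)


def brute_force_greedy(contigs, pairs, id_cut=0.95, cov_cut=0.80):
    """Independent re-statement of the greedy-centroid definition."""
    best = {}
    for a, b, i, c in pairs:
        k = tuple(sorted((a, b)))
        if k not in best or (i, c) > best[k]:
            best[k] = (i, c)
    order = sorted(contigs, key=lambda x: (-x.length_nt, x.contig_id))
    rep = {}
    reps = []
    for c in order:
        for r in reps:
            e = best.get(tuple(sorted((c.contig_id, r))))
            if e and e[0] > id_cut and e[1] >= cov_cut:
                rep[c.contig_id] = r
                break
        else:
            reps.append(c.contig_id)
            rep[c.contig_id] = c.contig_id
    return rep


class TestRpkm:
    def test_formula(self):
        counts = CountTable(counts={("c1", "s1"): 1000}, sample_totals={"s1": 10**6})
        m = compute_rpkm(counts, [contig("c1", 2000)])
        assert m.rpkm.at["c1", "s1"] == pytest.approx(500.0)

    def test_zero_reads(self):
        counts = CountTable(counts={("c1", "s1"): 0}, sample_totals={"s1": 10**6})
        m = compute_rpkm(counts, [contig("c1", 2000)])
        assert m.rpkm.at["c1", "s1"] == 0.0

    def test_scale_invariance(self):
        counts = CountTable(
            counts={("c1", "s1"): 100, ("c2", "s1"): 300}, sample_totals={"s1": 10_000}
        )
        doubled = CountTable(
            counts={("c1", "s1"): 200, ("c2", "s1"): 600}, sample_totals={"s1": 20_000}
        )
        contigs = [contig("c1", 2000), contig("c2", 4000)]
        a = compute_rpkm(counts, contigs).rpkm
        b = compute_rpkm(doubled, contigs).rpkm
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_unknown_contig_rejected(self):
        counts = CountTable(counts={("ghost", "s1"): 1}, sample_totals={"s1": 100})
        with pytest.raises(ValueError, match="unknown contig"):
            compute_rpkm(counts, [contig("c1")])

    def test_total_is_row_sum(self):
        counts = CountTable(
            counts={("c1", "s1"): 10, ("c1", "s2"): 30}, sample_totals={"s1": 1000, "s2": 1000}
        )
        m = compute_rpkm(counts, [contig("c1", 1000)])
        assert m.contig_total["c1"] == pytest.approx(m.rpkm.loc["c1"].sum())


class TestDereplicate:
    def test_identical_pair_clusters(self):
        contigs = [contig("a", 3000), contig("b", 3000)]
        res = dereplicate(contigs, [("a", "b", 1.0, 1.0)])
        assert res.n_clusters() == 1
        assert res.representative["b"] == "a"  # tie broken lexicographically

    def test_below_identity_stays_apart(self):
        contigs = [contig("a"), contig("b")]
        res = dereplicate(contigs, [("a", "b", 0.90, 1.0)])
        assert res.n_clusters() == 2

    def test_identity_boundary_is_strict(self):
        contigs = [contig("a"), contig("b")]
        assert dereplicate(contigs, [("a", "b", 0.95, 1.0)]).n_clusters() == 2
        assert dereplicate(contigs, [("a", "b", 0.951, 1.0)]).n_clusters() == 1

    def test_planted_cluster_structure(self):
        # 8 contigs with planted 3/2/1/1/1 partition
        lengths = {"a": 9000, "a1": 8000, "a2": 7000, "b": 6000, "b1": 5500,
                   "c": 5000, "d": 4500, "e": 4000}
        contigs = [contig(k, v) for k, v in lengths.items()]
        pairs = [("a", "a1", 0.99, 1.0), ("a", "a2", 0.98, 0.9),
                 ("b", "b1", 0.97, 1.0)]
        res = dereplicate(contigs, pairs)
        clusters = {r: sorted(m) for r, m in res.clusters.items()}
        assert clusters == {"a": ["a", "a1", "a2"], "b": ["b", "b1"],
                            "c": ["c"], "d": ["d"], "e": ["e"]}
        assert res.representative == brute_force_greedy(contigs, pairs)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            contigs = [contig(f"c{i}", int(rng.integers(2000, 9001))) for i in range(n)]
            pairs = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        pairs.append(
                            (f"c{i}", f"c{j}", float(rng.uniform(0.9, 1.0)), float(rng.uniform(0.6, 1.0)))
                        )
            res = dereplicate(contigs, pairs)
            assert res.representative == brute_force_greedy(contigs, pairs)
            # invariant under pair-order permutation
            res2 = dereplicate(contigs, pairs[::-1])
            assert res2.representative == res.representative

    def test_unknown_contig_in_pair(self):
        with pytest.raises(ValueError, match="unknown"):
            dereplicate([contig("a")], [("a", "zz", 0.99, 1.0)])


def classification(cid, label, clade=None):
    stage = Stage.NONE if label is Label.UNCLASSIFIED else Stage.SORTER
    if label is not Label.UNCLASSIFIED and label is not Label.PHAGE:
        stage = Stage.HOMOLOGY_PHROG
    if label is Label.INOVIRUS:
        stage = Stage.INOVIRUS
    return ClassificationRecord(cid, label, stage, PassId.HIGH_ABUNDANCE, clade)


class TestCladeMatrix:
    def _matrix(self, totals):
        counts = CountTable(
            counts={(cid, "s1"): r for cid, r in totals.items()},
            sample_totals={"s1": 10**6},
        )
        contigs = [contig(cid, 1000) for cid in totals]
        return compute_rpkm(counts, contigs)

    def test_single_clade_holds_everything(self):
        m = self._matrix({"c1": 500_000, "c2": 400_000})
        classes = [classification("c1", Label.PHAGE), classification("c2", Label.PHAGE)]
        grouped, shares = clade_matrix(m, classes, top_cut=100.0)
        assert list(grouped.index) == ["Caudovirales"]
        assert shares["Caudovirales"] == pytest.approx(100.0)

    def test_planted_shares_recovered(self):
        # shares 30/21/7/42 planted directly as read mass on equal-length contigs
        reads = {"t": 300_000, "p": 210_000, "nb": 70_000, "cd": 420_000}
        m = self._matrix(reads)
        classes = [
            classification("t", Label.INOVIRUS),
            classification("p", Label.PHAGE, clade="Petitvirales"),
            classification("nb", Label.EUK_VIRUS),
            classification("cd", Label.PHAGE, clade="Caudovirales"),
        ]
        grouped, shares = clade_matrix(m, classes, top_cut=100.0)
        assert shares["Tubulavirales"] == pytest.approx(30.0)
        assert shares["Petitvirales"] == pytest.approx(21.0)
        assert shares["non-bacterial viruses"] == pytest.approx(7.0)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)
        # conservation: cell sums equal the selected totals exactly
        assert grouped.to_numpy().sum() == pytest.approx(m.rpkm.to_numpy().sum())

    def test_top_cut_infinity_empties_matrix(self):
        m = self._matrix({"c1": 1000})
        grouped, shares = clade_matrix(m, [classification("c1", Label.PHAGE)], top_cut=np.inf)
        assert grouped.empty

    def test_missing_classification_is_error(self):
        m = self._matrix({"c1": 500_000})
        with pytest.raises(ValueError, match="missing classification"):
            clade_matrix(m, [], top_cut=100.0)


class TestCompareGroups:
    def _grouped(self, values):
        import pandas as pd

        return pd.DataFrame({f"s{i}": {"Caudovirales": v} for i, v in enumerate(values)})

    def test_identical_groups_p_one(self):
        g = self._grouped([5.0, 5.0, 5.0, 5.0])
        _, p = compare_groups(g, ["s0", "s1"], ["s2", "s3"], "Caudovirales")
        assert p == pytest.approx(1.0)

    def test_forced_separation(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95] + [101.0, 101.1, 100.9, 101.05, 100.95]
        g = self._grouped(vals)
        _, p = compare_groups(g, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)], "Caudovirales")
        assert p < 0.001

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(19)
        a = rng.normal(10, 2, size=6)
        b = rng.normal(12, 3, size=5)
        g = self._grouped(list(a) + list(b))
        stat, p = compare_groups(
            g, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 11)], "Caudovirales"
        )
        # closed-form Welch statistic and Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        assert stat == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_overlapping_groups_rejected(self):
        g = self._grouped([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(g, ["s0", "s1"], ["s1", "s2"], "Caudovirales")
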