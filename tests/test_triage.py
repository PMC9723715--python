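"""The priority cascade, the protein-profile rule and the tally arithmetic."""

import random

import pytest

from virotriage import (
    Compartment,
    ContigRecord,
    EvidenceRecord,
    EvidenceSource,
    Label,
    PassId,
    Stage,
    SubjectType,
    apply_stage,
    phrog_rule,
    run_cascade,
    tally,
)
from virotriage.reference import both_pass_tally, first_pass_tally


def ev(cid, source, category="x", subject=SubjectType.NA, e=None, gene=None):
    return EvidenceRecord(cid, source, category, subject, e, gene)


def contig(cid, length=3000):
    return ContigRecord(cid, "", Compartment.VIROME, length)


class TestPhrogRule:
    @pytest.mark.parametrize(
        "n_orfs,e_values,expected",
        [
            (10, [1e-15] * 4, True),  # 0.40 >= 0.35
            (4, [1e-20] * 4, False),  # fewer than 5 ORFs
            (20, [1e-15] * 6 + [1e-5] * 3, False),  # weak hits excluded: 6/20 < 0.35
            (20, [1e-15] * 7, True),  # 7/20 = 0.35 inclusive boundary
            (5, [], False),
        ],
    )
    def test_rule(self, n_orfs, e_values, expected):
        assert phrog_rule(n_orfs, len(e_values), e_values) is expected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            phrog_rule(3, 4, [1e-20] * 4)


class TestApplyStage:
    def test_sorter_accepts_all_categories(self):
        for cat in ("cat1", "cat2", "cat3"):
            labels = apply_stage(["c1"], [ev("c1", EvidenceSource.SORTER, cat)], Stage.SORTER)
            assert labels == {"c1": Label.PHAGE}

    def test_prophage_override(self):
        evidence = [
            ev("c1", EvidenceSource.NUCL_HOMOLOGY, "nt", SubjectType.BACTERIAL, 1e-30),
        ] + [
            ev("c1", EvidenceSource.PROT_PROFILE, f"p{i}", SubjectType.PHAGE, 1e-15, gene=i)
            for i in range(5)
        ]
        labels = apply_stage(
            ["c1"], evidence, Stage.HOMOLOGY_PHROG, orf_counts={"c1": 10}
        )
        assert labels == {"c1": Label.PHAGE}

    def test_bacterial_kept_without_phage_proteins(self):
        evidence = [ev("c1", EvidenceSource.NUCL_HOMOLOGY, "nt", SubjectType.BACTERIAL, 1e-30)]
        labels = apply_stage(["c1"], evidence, Stage.HOMOLOGY_PHROG, orf_counts={"c1": 10})
        assert labels == {"c1": Label.BACTERIAL}

    def test_weak_nucleotide_hit_ignored(self):
        evidence = [ev("c1", EvidenceSource.NUCL_HOMOLOGY, "nt", SubjectType.PLASMID, 1e-10)]
        assert apply_stage(["c1"], evidence, Stage.HOMOLOGY_PHROG, orf_counts={"c1": 10}) == {}

    def test_duplicate_rows_lowest_e_value_wins(self):
        rows = [
            ev("c1", EvidenceSource.NUCL_HOMOLOGY, "a", SubjectType.PLASMID, 1e-20),
            ev("c1", EvidenceSource.NUCL_HOMOLOGY, "b", SubjectType.EUK_VIRUS, 1e-40),
        ]
        for perm in (rows, rows[::-1]):
            labels = apply_stage(["c1"], perm, Stage.HOMOLOGY_PHROG, orf_counts={"c1": 3})
            assert labels == {"c1": Label.EUK_VIRUS}

    def test_no_evidence_leaves_unlabeled(self):
        assert apply_stage(["c1"], [], Stage.SORTER) == {}


class TestRunCascade:
    def test_stage_priority_sorter_beats_secondary(self):
        contigs = [contig("c1")]
        evidence = [
            ev("c1", EvidenceSource.SECONDARY, "phage", SubjectType.PHAGE),
            ev("c1", EvidenceSource.SORTER, "cat2", SubjectType.PHAGE),
        ]
        (rec,) = run_cascade(contigs, evidence, {"c1": 500.0}, orf_counts={"c1": 5})
        assert rec.stage is Stage.SORTER and rec.label is Label.PHAGE
        assert rec.pass_id is PassId.HIGH_ABUNDANCE

    def test_low_pass_skips_sorter_and_homology(self):
        contigs = [contig("c1"), contig("c2")]
        evidence = [
            ev("c1", EvidenceSource.SORTER, "cat1", SubjectType.PHAGE),
            ev("c2", EvidenceSource.SECONDARY, "phage", SubjectType.PHAGE),
        ]
        recs = {
            r.contig_id: r
            for r in run_cascade(
                contigs, evidence, {"c1": 10.0, "c2": 10.0}, orf_counts={"c1": 5, "c2": 5}
            )
        }
        # sorter evidence is not consulted in the low-abundance pass
        assert recs["c1"].label is Label.UNCLASSIFIED
        assert recs["c2"].label is Label.PHAGE and recs["c2"].stage is Stage.SECONDARY
        assert recs["c2"].pass_id is PassId.LOW_ABUNDANCE

    def test_empty_evidence_all_unclassified(self):
        contigs = [contig(f"c{i}") for i in range(4)]
        recs = run_cascade(contigs, [], {c.contig_id: 200.0 for c in contigs}, orf_counts={})
        assert all(r.label is Label.UNCLASSIFIED and r.stage is Stage.NONE for r in recs)

    def test_missing_abundance_is_error(self):
        with pytest.raises(ValueError, match="abundance"):
            run_cascade([contig("c1")], [], {}, orf_counts={})

    def test_evidence_order_never_changes_labels(self, small_community):
        from virotriage import emulate_evidence
        from virotriage.io import Compartment as C

        ev_vp, _ = emulate_evidence(small_community)
        vp = small_community.by_compartment(C.VIROME)
        abundance = {d["contig_id"]: d["T_virome"] for d in small_community.info}
        base = run_cascade(vp, ev_vp, abundance, orf_counts=small_community.orf_counts())
        rng = random.Random(5)
        for _ in range(3):
            shuffled = ev_vp[:]
            rng.shuffle(shuffled)
            again = run_cascade(vp, shuffled, abundance, orf_counts=small_community.orf_counts())
            assert [(r.contig_id, r.label, r.stage) for r in again] == [
                (r.contig_id, r.label, r.stage) for r in base
            ]

    def test_adding_evidence_only_resolves_unclassified(self):
        contigs = [contig("c1"), contig("c2")]
        abundance = {"c1": 500.0, "c2": 500.0}
        evidence = [ev("c1", EvidenceSource.SORTER, "cat1", SubjectType.PHAGE)]
        before = {r.contig_id: r.label for r in run_cascade(contigs, evidence, abundance, orf_counts={})}
        more = evidence + [ev("c2", EvidenceSource.SECONDARY, "virus", SubjectType.EUK_VIRUS)]
        after = {r.contig_id: r.label for r in run_cascade(contigs, more, abundance, orf_counts={})}
        assert before["c1"] == after["c1"]
        assert before["c2"] is Label.UNCLASSIFIED and after["c2"] is Label.EUK_VIRUS


class TestTally:
    def test_published_first_pass_accounting(self):
        t = first_pass_tally()
        assert t.total == 2480
        assert t.viral == 1951
        assert t.classified == 2031
        pct = t.percentages()
        assert pct["pct_classified"] == 82
        assert pct["pct_unclassified"] == 18
        assert pct["pct_phage_of_classified"] == 83
        assert pct["pct_euk_virus_of_classified"] == 13

    def test_published_both_pass_accounting(self):
        t = both_pass_tally()
        assert t.total == 7755
        assert t.viral == 5806
        assert t.percentages()["pct_viral_overall"] == 75

    def test_single_record(self):
        from virotriage import ClassificationRecord

        t = tally([ClassificationRecord("c1", Label.PHAGE, Stage.SORTER, PassId.HIGH_ABUNDANCE)])
        pct = t.percentages()
        assert pct["pct_classified"] == 100 and pct["pct_phage_of_classified"] == 100

    def test_conservation(self, small_community):
        from virotriage import emulate_evidence
        from virotriage.io import Compartment as C

        ev_vp, _ = emulate_evidence(small_community)
        vp = small_community.by_compartment(C.VIROME)
        abundance = {d["contig_id"]: d["T_virome"] for d in small_community.info}
        recs = run_cascade(vp, ev_vp, abundance, orf_counts=small_community.orf_counts())
        t = tally(recs)
        assert t.total == len(vp)
        bacterial = sum(n for (_, _, lab), n in t.counts.items() if lab is Label.BACTERIAL)
        plasmid = sum(n for (_, _, lab), n in t.counts.items() if lab is Label.PLASMID)
        assert t.viral + bacterial + plasmid + t.unclassified == t.total

    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            tally(stage_counts_override={(PassId.HIGH_ABUNDANCE, Stage.SORTER, Label.PHAGE): -1})
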