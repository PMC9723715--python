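"""Three-tier ARG merging, contig attribution and density/detection limits."""

import pytest

from virotriage import (
    ActivityRecord,
    ActivityStatus,
    ClassificationRecord,
    Criterion,
    EvidenceRecord,
    EvidenceSource,
    Label,
    PassId,
    Stage,
    SubjectType,
    Tier,
    call_args,
    classify_arg_contigs,
    confirmed_hits,
    density_report,
    enrichment_ratio,
)
from virotriage._util import round_half_away


def arg_row(cid, source, name, gene=0, e=1e-50):
    e_val = None if source is EvidenceSource.ARG_CONFIRMED else e
    return EvidenceRecord(cid, source, name, SubjectType.NA, e_val, gene)


class TestCallArgs:
    def test_three_sources_merge_to_one_hit(self):
        rows = [
            arg_row("c1", EvidenceSource.ARG_PROFILE, "tet(W)", 3, 1e-80),
            arg_row("c1", EvidenceSource.ARG_HOMOLOGY, "tet(W)", 3, 1e-40),
            arg_row("c1", EvidenceSource.ARG_CONFIRMED, "tet(W)", 3),
        ]
        (hit,) = call_args(rows)
        assert hit.tiers == {Tier.SENSITIVE, Tier.HOMOLOGY, Tier.CONFIRMED}
        assert hit.arg_name == "tet(W)" and hit.e_value == 1e-80

    def test_merge_is_order_independent_and_idempotent(self):
        rows = [
            arg_row("c1", EvidenceSource.ARG_PROFILE, "TEM", 1),
            arg_row("c1", EvidenceSource.ARG_CONFIRMED, "TEM", 1),
            arg_row("c1", EvidenceSource.ARG_PROFILE, "ABC_efflux", 2),
        ]
        a = call_args(rows)
        b = call_args(rows[::-1])
        c = call_args(rows + rows)  # duplicated evidence adds nothing
        assert a == b == c
        assert len(a) == 2

    def test_published_virome_census_structure(self):
        """Eight ARG-positive contigs: 10 profile ARGs, 3 also confirmed,
        plus one confirmed-only tet(40); 4 contigs end up with a confirmed
        tier; transporter families are flagged low-confidence."""
        rows = [
            arg_row("VP8_N183", EvidenceSource.ARG_PROFILE, "ABC_efflux", 0, 2.9e-97),
            arg_row("VP2_N298", EvidenceSource.ARG_PROFILE, "MexH", 0, 2.2e-42),
            arg_row("VP2_N298", EvidenceSource.ARG_PROFILE, "RND_efflux", 1, 1e-180),
            arg_row("VP7_N302", EvidenceSource.ARG_PROFILE, "ANT9", 1, 1.3e-80),
            arg_row("VP7_N302", EvidenceSource.ARG_CONFIRMED, "tet(40)", 0),  # confirmed-only
            arg_row("VP7_N1", EvidenceSource.ARG_PROFILE, "ABC_efflux", 0, 7.9e-89),
            arg_row("VP7_N2", EvidenceSource.ARG_PROFILE, "ABC_efflux", 0, 5.1e-84),
            arg_row("VP7_N3", EvidenceSource.ARG_PROFILE, "tet(W)", 0, 1e-200),
            arg_row("VP7_N3", EvidenceSource.ARG_CONFIRMED, "tet(W)", 0),
            arg_row("VP8_N804", EvidenceSource.ARG_PROFILE, "TEM", 0, 1.8e-205),
            arg_row("VP8_N804", EvidenceSource.ARG_CONFIRMED, "TEM", 0),
            arg_row("VP8_N804", EvidenceSource.ARG_PROFILE, "tet_MFS_efflux", 1, 1.9e-80),
            arg_row("VP12_N394", EvidenceSource.ARG_PROFILE, "APH3'", 0, 3.2e-113),
            arg_row("VP12_N394", EvidenceSource.ARG_CONFIRMED, "APH3'", 0),
        ]
        hits = call_args(rows)
        assert len({h.contig_id for h in hits}) == 8
        confirmed_contigs = {h.contig_id for h in hits if Tier.CONFIRMED in h.tiers}
        assert confirmed_contigs == {"VP7_N302", "VP7_N3", "VP8_N804", "VP12_N394"}
        assert sum(1 for h in hits if h.low_confidence) == 5  # the transporter calls

    def test_missing_gene_index_rejected(self):
        bad = EvidenceRecord("c1", EvidenceSource.ARG_PROFILE, "TEM", SubjectType.NA, 1e-50, None)
        with pytest.raises(ValueError, match="gene_index"):
            call_args([bad])

    def test_empty_evidence(self):
        assert call_args([]) == []

    def test_non_arg_evidence_ignored(self):
        rows = [EvidenceRecord("c1", EvidenceSource.SORTER, "cat1", SubjectType.PHAGE)]
        assert call_args(rows) == []


def vp_class(cid, label=Label.BACTERIAL):
    stage = Stage.NONE if label is Label.UNCLASSIFIED else Stage.HOMOLOGY_PHROG
    return ClassificationRecord(cid, label, stage, PassId.HIGH_ABUNDANCE)


def p_act(cid, viral, active=False):
    rec = ActivityRecord(cid, viral, {Criterion.TAXON_VIRAL} if viral else set())
    if viral:
        rec.status = ActivityStatus.ACTIVE if active else ActivityStatus.DORMANT
    return rec


class TestClassifyArgContigs:
    def test_dormant_prophage_attribution_and_fraction(self):
        # 5 ARG contigs in the microbiome universe, 1 on a dormant prophage
        activity = [p_act(f"p{i}", viral=i < 3) for i in range(10)]
        hits = call_args(
            [arg_row(f"p{i}", EvidenceSource.ARG_PROFILE, "tet(W)", 0) for i in (0, 5, 6, 7, 8)]
        )
        tab = classify_arg_contigs(hits, [], activity)
        assert tab.table.loc[("viral", "microbiome", "dormant"), "contigs"] == 1
        assert tab.table.loc[("bacterial", "microbiome", "NA"), "contigs"] == 4
        assert tab.viral_fraction["microbiome"] == pytest.approx(1 / 3)

    def test_virome_args_none_on_phages(self):
        classes = [vp_class("v1"), vp_class("v2", Label.PLASMID), vp_class("v3", Label.PHAGE)]
        hits = call_args(
            [arg_row("v1", EvidenceSource.ARG_PROFILE, "TEM", 0),
             arg_row("v2", EvidenceSource.ARG_PROFILE, "APH3'", 0)]
        )
        tab = classify_arg_contigs(hits, classes, [])
        assert ("viral", "virome", "NA") not in tab.table.index
        assert tab.viral_fraction["virome"] == 0.0

    def test_no_args_empty_table(self):
        tab = classify_arg_contigs([], [vp_class("v1")], [])
        assert tab.table.empty

    def test_unknown_contig_rejected(self):
        hits = call_args([arg_row("ghost", EvidenceSource.ARG_PROFILE, "TEM", 0)])
        with pytest.raises(ValueError, match="missing from both"):
            classify_arg_contigs(hits, [], [])


def hits_n(n):
    return call_args(
        [arg_row(f"c{i}", EvidenceSource.ARG_CONFIRMED, "tet(W)", 0) for i in range(n)]
    )


class TestDensityReport:
    def test_per_mb_and_bacterial_genome_extrapolation(self):
        # 0.18 ARG/Mb -> 0.54 per 3-Mb genome, printed as 0.5 at one decimal
        rep = density_report(hits_n(18), n_genes=100_000, assembled_mb=100.0,
                             compartment="microbiome")
        assert rep.per_mb == pytest.approx(0.18)
        assert round_half_away(rep.per_bacterial_genome, 1) == 0.5

    def test_zero_args_detection_limits(self):
        rep = density_report([], n_genes=80_000, assembled_mb=66.7,
                             compartment="virome", n_contigs=5806)
        assert rep.is_upper_bound
        assert rep.detection_limit_fraction == pytest.approx(100 / 5806)
        assert rep.detection_limit_fraction <= 0.02
        assert rep.detection_limit_per_mb == pytest.approx(1 / 66.7)

    def test_phage_genome_bound_and_enrichment(self):
        # per-ORF bound 1.2e-5 with 30 ORFs/genome -> 3.6e-4 per genome;
        # against 0.54 per bacterial genome that is a 1500-fold enrichment
        viral = density_report([], n_genes=83_334, assembled_mb=66.7,
                               compartment="virome", n_contigs=5806)
        assert viral.per_gene == pytest.approx(1.2e-5, rel=1e-4)
        assert viral.per_phage_genome_bound == pytest.approx(3.6e-4, rel=1e-4)
        bact = density_report(hits_n(18), n_genes=100_000, assembled_mb=100.0,
                              compartment="microbiome")
        fold = enrichment_ratio(bact, viral)
        assert fold == pytest.approx(1500.0, rel=1e-3)
        assert fold >= 1000

    def test_rate_scaling(self):
        a = density_report(hits_n(4), 1000, 10.0, "x")
        b = density_report(hits_n(8), 2000, 20.0, "x")
        assert a.per_mb == pytest.approx(b.per_mb)
        assert a.per_gene == pytest.approx(b.per_gene)

    def test_detection_limit_monotone_in_assembled_mb(self):
        limits = [
            density_report([], 1000, mb, "x", n_contigs=100).detection_limit_per_mb
            for mb in (1.0, 5.0, 25.0, 125.0)
        ]
        assert limits == sorted(limits, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            density_report([], 1000, 0.0, "x")
        with pytest.raises(ValueError):
            density_report([], 0, 1.0, "x")

    def test_confirmed_filter_excludes_transporters(self):
        rows = [
            arg_row("c1", EvidenceSource.ARG_PROFILE, "ABC_efflux", 0),
            arg_row("c1", EvidenceSource.ARG_CONFIRMED, "ABC_efflux", 0),
            arg_row("c2", EvidenceSource.ARG_CONFIRMED, "tet(W)", 0),
        ]
        kept = confirmed_hits(call_args(rows))
        assert [h.contig_id for h in kept] == ["c2"]
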