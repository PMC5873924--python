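"""Intron-retention statistics and junction-defined event calling."""

import numpy as np
import pandas as pd
import pytest

from splicedelta.alignments import DepthProfile
from splicedelta.annotation import AnnotationSet, GeneModel, GenomicInterval
from splicedelta.events import (
    ExclusionList,
    as_ratio,
    classify_as_events,
    classify_introns,
    enumerate_as_events,
    expression_ratio,
    intron_retention_ratio,
    summarize_events,
)

from oracles import welch_oracle


def _gene(exon_coords, gene_id="g", strand="+"):
    exons = [GenomicInterval("chr1", s, e, strand) for s, e in exon_coords]
    return GeneModel(gene_id, "chr1", strand, [exons])


def _depth(profile_spec, length=2000):
    depth = DepthProfile({"chr1": length})
    for (start, end), value in profile_spec:
        depth.depth["chr1"][start - 1 : end] = value
    return depth


THREE_EXON = [(101, 200), (301, 400), (501, 600)]


class TestIntronRetentionRatio:
    def test_uniform_depths_give_direct_quotient(self):
        gene = _gene(THREE_EXON)
        depth = _depth([((101, 200), 40), ((201, 300), 10), ((301, 400), 40)])
        assert intron_retention_ratio(depth, gene, 0) == pytest.approx(0.25)

    def test_fully_spliced_intron_has_ratio_zero(self):
        gene = _gene(THREE_EXON)
        depth = _depth([((101, 200), 40), ((301, 400), 40)])
        assert intron_retention_ratio(depth, gene, 0) == 0.0

    def test_zero_flank_depth_is_flagged_not_coerced(self):
        gene = _gene(THREE_EXON)
        depth = _depth([((201, 300), 10)])
        assert np.isnan(intron_retention_ratio(depth, gene, 0))

    def test_unequal_flank_depths_pool_base_wise(self):
        gene = _gene([(101, 200), (301, 400), (501, 700)])  # flanks 100 vs 200 nt
        depth = _depth([((301, 400), 30), ((401, 500), 10), ((501, 700), 60)])
        # pooled flank mean = (100*30 + 200*60) / 300 = 50
        assert intron_retention_ratio(depth, gene, 1) == pytest.approx(10 / 50)
        # per-exon-mean alternative = (30 + 60) / 2 = 45
        assert intron_retention_ratio(
            depth, gene, 1, pool_flanks=False
        ) == pytest.approx(10 / 45)

    def test_depth_scale_invariance(self):
        gene = _gene(THREE_EXON)
        base = _depth([((101, 200), 40), ((201, 300), 10), ((301, 400), 40)])
        scaled = _depth([((101, 200), 40), ((201, 300), 10), ((301, 400), 40)])
        scaled.depth["chr1"] = scaled.depth["chr1"] * 7
        assert intron_retention_ratio(base, gene, 0) == pytest.approx(
            intron_retention_ratio(scaled, gene, 0)
        )


def _ratio_table(wt, mut, start=201, end=300):
    row = {
        "gene_id": "g",
        "chrom": "chr1",
        "strand": "+",
        "intron_index": 0,
        "start": start,
        "end": end,
    }
    for i, v in enumerate(wt):
        row[f"ratio_wt_{i + 1}"] = v
    for i, v in enumerate(mut):
        row[f"ratio_mut_{i + 1}"] = v
    return pd.DataFrame([row])


GROUPS = {f"wt_{i}": "wt" for i in (1, 2, 3)} | {f"mut_{i}": "mut" for i in (1, 2, 3)}


class TestClassifyIntrons:
    def test_threefold_significant_rise_is_ir(self):
        wt, mut = (0.10, 0.11, 0.09), (0.30, 0.31, 0.29)
        result = classify_introns(_ratio_table(wt, mut), GROUPS)
        eps = 1e-6
        _, _, p_ref = welch_oracle(
            [np.log2(v + eps) for v in mut], [np.log2(v + eps) for v in wt]
        )
        assert result.loc[0, "p_value"] == pytest.approx(p_ref, abs=1e-12)
        assert p_ref < 0.01
        assert result.loc[0, "call"] == "IR"

    def test_raw_scale_option_matches_raw_welch_oracle(self):
        wt, mut = (0.10, 0.11, 0.09), (0.30, 0.31, 0.29)
        result = classify_introns(_ratio_table(wt, mut), GROUPS, use_log=False)
        _, _, p_ref = welch_oracle(list(mut), list(wt))
        assert result.loc[0, "p_value"] == pytest.approx(p_ref, abs=1e-12)
        assert result.loc[0, "call"] == "IR"

    def test_identical_groups_are_not_called(self):
        wt = (0.2, 0.25, 0.3)
        result = classify_introns(_ratio_table(wt, wt), GROUPS)
        assert result.loc[0, "p_value"] == 1.0
        assert result.loc[0, "call"] == "none"

    def test_subthreshold_fold_gate_blocks_significant_call(self):
        wt = (0.100, 0.1001, 0.0999)
        mut = (0.190, 0.1901, 0.1899)  # 1.9x with tiny p
        result = classify_introns(_ratio_table(wt, mut), GROUPS)
        assert result.loc[0, "p_value"] < 1e-5
        assert result.loc[0, "call"] == "none"

    def test_mirror_change_is_mes(self):
        wt, mut = (0.30, 0.31, 0.29), (0.10, 0.11, 0.09)
        result = classify_introns(_ratio_table(wt, mut), GROUPS)
        assert result.loc[0, "call"] == "MES"

    def test_flagged_replicate_excludes_intron_with_reason(self):
        wt, mut = (0.1, np.nan, 0.09), (0.3, 0.31, 0.29)
        result = classify_introns(_ratio_table(wt, mut), GROUPS)
        assert result.loc[0, "call"] == "none"
        assert result.loc[0, "excluded_reason"] == "undefined_ratio"

    def test_exclusion_list_drops_intron_before_testing(self):
        wt, mut = (0.10, 0.11, 0.09), (0.50, 0.51, 0.49)
        exclusion = ExclusionList([("chr1", 250, 260)])
        result = classify_introns(
            _ratio_table(wt, mut), GROUPS, exclusion=exclusion
        )
        assert result.loc[0, "call"] == "none"
        assert result.loc[0, "excluded_reason"] == "exclusion_list"


class TestRatios:
    def test_as_ratio_plain_and_pseudocounted(self):
        assert as_ratio(20, 5, pseudocount=0) == 4.0
        assert as_ratio(0, 0) == 1.0
        assert np.log2(as_ratio(0, 0)) == 0.0

    def test_expression_ratio_plain_and_zero_support(self):
        assert expression_ratio(20, 200, pseudocount=0) == pytest.approx(0.1)
        assert expression_ratio(0, 99) == pytest.approx(1 / 100)


class TestEnumerateEvents:
    def _junctions(self, counter):
        return {s: dict(counter) for s in GROUPS}

    def test_annotated_junction_is_not_a_candidate(self):
        gene = _gene(THREE_EXON)
        junctions = self._junctions({("chr1", 200, 301): 50})
        events = enumerate_as_events(junctions, AnnotationSet([gene]))
        assert len(events) == 0

    def test_skip_junction_defines_exon_skip_candidate(self):
        gene = _gene(THREE_EXON)
        junctions = self._junctions(
            {("chr1", 200, 501): 5, ("chr1", 200, 301): 30, ("chr1", 400, 501): 28}
        )
        events = enumerate_as_events(junctions, AnnotationSet([gene]))
        assert list(events["event_type"]) == ["exon_skip"]
        row = events.iloc[0]
        assert (row["feature_start"], row["feature_end"]) == (301, 400)
        assert row["supp_wt_1"] == 5
        assert row["nonsupp_wt_1"] == 58  # both flanking annotated junctions

    def test_shifted_acceptor_is_alt_acceptor_on_plus_strand(self):
        gene = _gene(THREE_EXON)
        junctions = self._junctions(
            {("chr1", 200, 298): 7, ("chr1", 200, 301): 40}
        )
        events = enumerate_as_events(junctions, AnnotationSet([gene]))
        assert list(events["event_type"]) == ["alt_acceptor"]
        row = events.iloc[0]
        assert (row["donor"], row["acceptor"]) == (200, 298)
        assert row["supp_wt_1"] == 7 and row["nonsupp_wt_1"] == 40

    def test_strand_flips_the_splice_site_label(self):
        gene = _gene(THREE_EXON, strand="-")
        junctions = self._junctions({("chr1", 200, 298): 7})
        events = enumerate_as_events(junctions, AnnotationSet([gene]))
        # left boundary unchanged, right boundary shifted; on '-' the right
        # (genomically downstream) boundary is the 5' donor side
        assert list(events["event_type"]) == ["alt_donor"]

    def test_both_boundaries_shifted_is_alt_both(self):
        gene = _gene(THREE_EXON)
        junctions = self._junctions({("chr1", 203, 298): 7})
        events = enumerate_as_events(junctions, AnnotationSet([gene]))
        assert list(events["event_type"]) == ["alt_both"]


def _candidate_frame(supp_wt, supp_mut, nonsupp_wt, nonsupp_mut):
    row = {
        "gene_id": "g",
        "chrom": "chr1",
        "strand": "+",
        "event_type": "alt_acceptor",
        "donor": 200,
        "acceptor": 298,
        "ref_donor": 200,
        "ref_acceptor": 301,
        "feature_start": 201,
        "feature_end": 300,
    }
    for i, v in enumerate(supp_wt):
        row[f"supp_wt_{i + 1}"] = v
    for i, v in enumerate(supp_mut):
        row[f"supp_mut_{i + 1}"] = v
    for i, v in enumerate(nonsupp_wt):
        row[f"nonsupp_wt_{i + 1}"] = v
    for i, v in enumerate(nonsupp_mut):
        row[f"nonsupp_mut_{i + 1}"] = v
    return pd.DataFrame([row])


def _uniq(values):
    return pd.DataFrame({s: [v] for s, v in zip(GROUPS, values)}, index=["g"])


class TestClassifyAsEvents:
    def test_identical_groups_unreported(self):
        cand = _candidate_frame((10, 12, 11), (10, 12, 11), (90, 88, 89), (90, 88, 89))
        result = classify_as_events(cand, _uniq([500] * 6), GROUPS)
        assert not result.loc[0, "reported"]
        assert result.loc[0, "call"] == "none"

    def test_strong_usage_shift_reported_enhanced(self):
        # wild type ~10% usage, mutant ~60% at ~100 junction reads
        cand = _candidate_frame(
            (10, 11, 9), (60, 62, 58), (90, 89, 91), (40, 38, 42)
        )
        uniq = _uniq([500, 510, 490, 505, 495, 500])
        result = classify_as_events(cand, uniq, GROUPS)
        assert result.loc[0, "p_as"] < 0.01 and result.loc[0, "p_expr"] < 0.01
        assert result.loc[0, "reported"]
        assert result.loc[0, "call"] == "enhanced"

    def test_single_passing_channel_is_not_reported(self):
        # AS ratio shifts sharply but supporting counts (hence expression
        # ratios) barely move: the dual test must stay silent
        cand = _candidate_frame(
            (30, 31, 29), (33, 34, 32), (90, 91, 89), (9, 10, 8)
        )
        uniq = _uniq([500, 500, 500, 500, 500, 500])
        result = classify_as_events(cand, uniq, GROUPS)
        assert result.loc[0, "p_as"] < 0.01
        assert result.loc[0, "p_expr"] >= 0.01
        assert not result.loc[0, "reported"]


class TestSummarize:
    def test_empty_results_give_all_zero_counts(self):
        gene = _gene(THREE_EXON)
        annotation = AnnotationSet([gene])
        summary = summarize_events(annotation)
        assert summary.empty or (summary["count"] == 0).all()

    def test_label_swap_exchanges_ir_and_mes_counts(self, small_result, small_cohort):
        ir = small_result.ir
        swapped_groups = {
            s: ("mut" if g == "wt" else "wt")
            for s, g in small_cohort.groups.items()
        }
        rev = classify_introns(
            ir[[c for c in ir.columns if not c.startswith(("mean_", "p_", "call", "excluded"))]],
            swapped_groups,
        )
        assert (ir["call"] == "IR").sum() == (rev["call"] == "MES").sum()
        assert (ir["call"] == "MES").sum() == (rev["call"] == "IR").sum()

    def test_percentages_use_feature_universe(self, small_result, small_cohort):
        summary = small_result.summary
        annotation = small_cohort.annotation
        ir_row = summary[summary["category"] == "IR"].iloc[0]
        assert ir_row["percent"] == pytest.approx(
            100.0 * ir_row["count"] / annotation.total_introns
        )
        es_row = summary[summary["category"] == "ES"].iloc[0]
        assert es_row["percent"] == pytest.approx(
            100.0 * es_row["count"] / annotation.total_internal_exons
        )
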