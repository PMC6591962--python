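"""Tau index, the five marker criteria, aggregation, HCC filtering, annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mctamap.markers import (
    DEFAULT_TISSUES,
    aggregate_markers,
    annotate_intragenic_tissue_genes,
    filter_hcc_safe_markers,
    panel_max_marker,
    percentile_nearest_rank,
    select_tissue_markers,
    tau_index,
)


class TestTau:
    def test_single_tissue_is_one(self):
        assert tau_index([1, 0, 0, 0, 0, 0, 0, 0]) == 1.0

    def test_uniform_is_zero(self):
        assert tau_index([5] * 8) == 0.0

    def test_derived_example(self):
        # (7 * (1 - 0.1)) / 7 = 0.9 — exactly at, hence excluded by, the
        # strictly-greater tau > 0.9 threshold
        assert tau_index([10, 1, 1, 1, 1, 1, 1, 1]) == pytest.approx(0.9)

    def test_all_zero_signalled(self):
        with pytest.raises(ValueError, match="all-zero"):
            tau_index([0, 0, 0])

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            tau_index([5.0])

    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=2, max_size=12)
           .filter(lambda v: max(v) > 0))
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, values):
        assert 0.0 <= tau_index(values) <= 1.0

    def test_strictly_decreasing_in_second_tissue(self):
        taus = [tau_index([10, s, 0, 0]) for s in (0, 2, 5, 9)]
        assert all(a > b for a, b in zip(taus, taus[1:]))


class TestNearestRankPercentile:
    def test_exact_zero_with_29_samples(self):
        # rank ceil(0.9 * 29) = 27 of the sorted values; with 3 positives
        # among 29 the 27th is positive, with 2 it is still zero
        vals = [0.0] * 26 + [1.0, 2.0, 3.0]
        assert percentile_nearest_rank(vals, 90) == 1.0
        vals = [0.0] * 27 + [1.0, 2.0]
        assert percentile_nearest_rank(vals, 90) == 0.0


def selection_inputs(rows: dict, wbc: dict, dist: dict):
    tissue_means = pd.DataFrame.from_dict(rows, orient="index",
                                          columns=list(DEFAULT_TISSUES))
    wbc_m = pd.DataFrame.from_dict(wbc, orient="index")
    distances = pd.Series(dist)
    return tissue_means, wbc_m, distances


class TestSelectTissueMarkers:
    def test_all_criteria_pass(self):
        tm, wbc, dist = selection_inputs(
            {"m1": [12, 0, 0, 0, 0, 0, 0, 0]},
            {"m1": [0.0] * 29},
            {"m1": 40},
        )
        ms = select_tissue_markers(tm, wbc, dist)
        assert ms.by_tissue["liver"] == ["m1"]
        assert ms.table.loc["m1", "tau"] == 1.0

    def test_wbc_percentile_rejects(self):
        tm, wbc, dist = selection_inputs(
            {"m1": [12, 0, 0, 0, 0, 0, 0, 0]},
            {"m1": [0.0] * 25 + [0.5] * 4},
            {"m1": 40},
        )
        ms = select_tissue_markers(tm, wbc, dist)
        assert ms.trail.loc["m1", "rejected_by"] == "iii:wbc"

    def test_liver_crossreactivity_rejects_nonliver(self):
        # pancreas marker with mean liver MePM 2 fails criterion (iv)
        tm, wbc, dist = selection_inputs(
            {"m1": [2, 0, 0, 0, 0, 40, 0, 0]},
            {"m1": [0.0] * 29},
            {"m1": 40},
        )
        ms = select_tissue_markers(tm, wbc, dist)
        assert ms.trail.loc["m1", "rejected_by"] == "iv:liver"

    def test_distance_rejects(self):
        tm, wbc, dist = selection_inputs(
            {"m1": [12, 0, 0, 0, 0, 0, 0, 0]},
            {"m1": [0.0] * 29},
            {"m1": 60},
        )
        ms = select_tissue_markers(tm, wbc, dist)
        assert ms.trail.loc["m1", "rejected_by"] == "v:distance"

    def test_lung_fallback_waives_tau(self):
        # lung marker shared with stomach: tau = (7 - 0.9)/7 < 0.9, so the
        # strict pass yields no lung markers and the tau-free retry fires
        tm, wbc, dist = selection_inputs(
            {"lungm": [0, 50, 45, 0, 0, 0, 0, 0]},
            {"lungm": [0.0] * 29},
            {"lungm": 30},
        )
        ms = select_tissue_markers(tm, wbc, dist)
        assert ms.by_tissue["lung"] == ["lungm"]
        assert bool(ms.table.loc["lungm", "tau_waived"])

    def test_planted_recovery_with_decoys(self, decoy_bundle):
        """Zero-leak synthetic panel: exactly the planted source-tissue
        markers survive; every decoy is rejected by its planted criterion."""
        b = decoy_bundle
        ms = select_tissue_markers(b.panel, b.wbc_training,
                                   b.marker_info["distance_bp"])
        genuine = set(b.marker_info.index[b.marker_info["decoy"] == ""])
        assert set(ms.table.index) == genuine
        for marker, info in b.marker_info[b.marker_info["decoy"] != ""].iterrows():
            reason = ms.trail.loc[marker, "rejected_by"]
            expected = {"far": "v:distance", "shared": "i:tau", "leaky": "iii:wbc"}
            assert reason == expected[info["decoy"]], (marker, info["decoy"], reason)
        for t, ms_keys in ms.by_tissue.items():
            assert all(b.marker_info.loc[k, "source_tissue"] == t for k in ms_keys)


class TestAggregate:
    def test_drop_max(self):
        assert aggregate_markers(pd.Series([7.0, 3.0, 2.0])) == 5.0

    def test_single_marker_passthrough(self):
        assert aggregate_markers(pd.Series([4.0])) == 4.0

    def test_all_zero(self):
        assert aggregate_markers(pd.Series([0.0, 0.0, 0.0])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_markers(pd.Series([], dtype=float))

    def test_fixed_exclusion_label(self):
        s = pd.Series({"a": 1.0, "b": 9.0, "c": 2.0})
        assert aggregate_markers(s, exclude="a") == 11.0

    @given(st.lists(st.floats(min_value=0, max_value=1e3), min_size=2, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_sum_identity(self, values):
        s = pd.Series(values)
        assert aggregate_markers(s) + s.max() == pytest.approx(s.sum())

    def test_panel_max_marker(self):
        panel = pd.DataFrame({"liver": [10.0, 90.0, 40.0]},
                             index=["a", "b", "c"])
        assert panel_max_marker(panel, ["a", "b", "c"], "liver") == "b"
        assert panel_max_marker(panel, ["a"], "liver") is None


class TestHccSafe:
    def marker_set(self, decoy_bundle):
        from mctamap.markers import select_tissue_markers
        b = decoy_bundle
        return select_tissue_markers(b.panel, b.wbc_training,
                                     b.marker_info["distance_bp"])

    def test_filters(self, decoy_bundle, rng):
        ms = self.marker_set(decoy_bundle)
        markers = ms.markers
        liver = [m for m in markers
                 if ms.table.loc[m, "source_tissue"] == "liver"]
        other = [m for m in markers if m not in liver]
        tumor = pd.DataFrame(0.0, index=markers,
                             columns=[f"t{i}" for i in range(10)])
        adjacent = pd.DataFrame(0.0, index=markers,
                                columns=[f"a{i}" for i in range(10)])
        # plant one tumor-hypermethylated liver marker (exact one-sided
        # p = 1/C(20,10) << 0.05) and one hot non-liver marker (p90 = 25)
        bad_liver, bad_other = liver[0], other[0]
        tumor.loc[bad_liver] = 100.0 + rng.normal(0, 1, 10)
        adjacent.loc[bad_liver] = rng.normal(0, 0.1, 10)
        tumor.loc[bad_other] = 25.0
        filtered = filter_hcc_safe_markers(ms, tumor, adjacent)
        assert bad_liver not in filtered.markers
        assert bad_other not in filtered.markers
        assert set(filtered.markers) == set(markers) - {bad_liver, bad_other}


class TestAnnotation:
    GENES = pd.DataFrame([
        dict(gene="G1", chrom="chr1", tss=1000, tes=5000, strand="+"),
        dict(gene="G2", chrom="chr2", tss=9000, tes=6000, strand="-"),
    ])
    EXPR = pd.DataFrame(
        {t: [1.0, 1.0] for t in DEFAULT_TISSUES}, index=["G1", "G2"])

    def markers_at(self, positions):
        return pd.DataFrame(
            [dict(marker=f"m{i}", chrom=c, pos=p, source_tissue=s)
             for i, (c, p, s) in enumerate(positions)]
        ).set_index("marker")

    def liver_expr(self):
        e = self.EXPR.copy()
        e.loc["G1", "liver"] = 500.0  # z >> 1.5 in liver
        return e

    def test_intragenic_marker_annotated(self):
        mk = self.markers_at([("chr1", 2000, "liver")])
        ann = annotate_intragenic_tissue_genes(mk, self.liver_expr(), self.GENES)
        assert ann.loc["m0", "intragenic"]
        assert ann.loc["m0", "gene"] == "G1"
        assert ann.loc["m0", "concordant"]

    def test_promoter_proximal_excluded(self):
        # 1100 < TSS + 300: upstream edge of the gene body
        mk = self.markers_at([("chr1", 1100, "liver")])
        ann = annotate_intragenic_tissue_genes(mk, self.liver_expr(), self.GENES)
        assert not ann.loc["m0", "intragenic"]

    def test_distant_marker_not_annotated(self):
        mk = self.markers_at([("chr1", 50_000, "liver")])
        ann = annotate_intragenic_tissue_genes(mk, self.liver_expr(), self.GENES)
        assert not ann.loc["m0", "intragenic"]

    def test_low_expression_not_annotated(self):
        mk = self.markers_at([("chr1", 2000, "liver")])
        ann = annotate_intragenic_tissue_genes(mk, self.EXPR, self.GENES)
        assert not ann.loc["m0", "intragenic"]

    def test_minus_strand_interval(self):
        e = self.EXPR.copy()
        e.loc["G2", "colon"] = 500.0
        # '-' gene body runs (tes - 300) .. (tss - 300)
        inside = self.markers_at([("chr2", 7000, "colon")])
        ann = annotate_intragenic_tissue_genes(inside, e, self.GENES)
        assert ann.loc["m0", "intragenic"]
        outside = self.markers_at([("chr2", 8800, "colon")])
        ann = annotate_intragenic_tissue_genes(outside, e, self.GENES)
        assert not ann.loc["m0", "intragenic"]
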