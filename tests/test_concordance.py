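"""Exon/intron concordance statistics and their sampling behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from intronkit import (build_pairwise_dataset, build_timecourse_dataset,
                       coefficient_of_variation, correlation_histogram,
                       intron_intron_extremes, intron_ratio_metrics,
                       spearman_rank, timecourse_correlation)
from intronkit.concordance import PairMatrices, ratio_strata_table

from conftest import make_design


def _pm(intron, exon, pairs=None, design=None):
    intron = np.asarray(intron, float)
    exon = np.asarray(exon, float)
    n_pairs, n_samples = intron.shape
    if pairs is None:
        pairs = pd.DataFrame({
            "intron_id": [f"i{k}" for k in range(n_pairs)],
            "transcript_id": ["tx"] * n_pairs})
    if design is None:
        tps = (0, 3, 6, 12, 24, 48)
        n_animals = n_samples // len(tps)
        design = make_design(n_animals, tps)
    samples = design.sort_values(["timepoint", "animal"]).reset_index(
        drop=True)
    return PairMatrices(pairs, intron, exon, samples)


class TestSpearman:
    def test_monotone_series(self):
        x = np.arange(1.0, 11.0)
        assert spearman_rank(x, 2 * x) == pytest.approx(1.0)
        assert spearman_rank(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert spearman_rank([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rank([1, 1, 1, 1], [1, 2, 3, 4])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_reference_implementation(self, xs, rnd):
        ys = xs[:]
        rnd.shuffle(ys)
        x, y = np.array(xs), np.array(ys)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        expected = stats.spearmanr(x, y).statistic
        assert spearman_rank(x, y) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        r = np.random.default_rng(2)
        x, y = r.random(20), r.random(20)
        base = spearman_rank(x, y)
        assert spearman_rank(np.exp(5 * x), y) == pytest.approx(base)
        assert spearman_rank(x, y ** 3) == pytest.approx(base)


class TestPairDatasets:
    def test_pooled_top_half_by_exonic_density(self):
        pm = _pm([[5.0], [5.0], [5.0], [5.0]], [[1.0], [2.0], [3.0], [4.0]],
                 design=make_design(1, (0,)))
        out = build_pairwise_dataset(pm, top_fraction=0.5)
        assert sorted(out["exon_density"]) == [3.0, 4.0]

    def test_both_zero_points_removed_before_ranking(self):
        pm = _pm([[0.0], [1.0]], [[0.0], [0.0]], design=make_design(1, (0,)))
        out = build_pairwise_dataset(pm, top_fraction=1.0)
        assert len(out) == 1
        assert out["intron_density"].iloc[0] == 1.0

    def test_top_fraction_one_is_identity_after_zero_removal(self):
        r = np.random.default_rng(0)
        pm = _pm(r.random((6, 42)) + 0.1, r.random((6, 42)) + 0.1,
                 pairs=pd.DataFrame({
                     "intron_id": [f"i{k}" for k in range(6)],
                     "transcript_id": ["tx"] * 6}))
        out = build_pairwise_dataset(pm, top_fraction=1.0)
        assert len(out) == 6 * 42

    def test_timecourse_filter_removes_all_zero_series(self):
        r = np.random.default_rng(0)
        intron = r.random((3, 42)) + 0.1
        intron[1] = 0.0
        pm = _pm(intron, r.random((3, 42)) + 0.1,
                 pairs=pd.DataFrame({
                     "intron_id": ["a", "b", "c"],
                     "transcript_id": ["tx"] * 3}))
        tc = build_timecourse_dataset(pm, top_fraction=1.0)
        assert set(tc.pairs["intron_id"]) == {"a", "c"}


class TestTimecourseCorrelation:
    def test_identical_series_all_in_top_bin(self):
        r = np.random.default_rng(1)
        m = r.random((5, 42))
        pm = _pm(m, m, pairs=pd.DataFrame({
            "intron_id": [f"i{k}" for k in range(5)],
            "transcript_id": ["tx"] * 5}))
        rho = timecourse_correlation(pm)
        assert np.allclose(rho["rho"], 1.0)
        hist = correlation_histogram(rho["rho"])
        assert hist.set_index("bin").loc["rho>0.5", "count"] == 5

    def test_histogram_percentages(self):
        rhos = np.array([-0.5, 0.0, 0.1, 0.3, 0.6, 0.9])
        hist = correlation_histogram(rhos).set_index("bin")
        assert hist.loc["rho<=0", "count"] == 2
        assert hist.loc["rho<=0", "pct"] == pytest.approx(33.3)
        assert hist["count"].sum() == 6


class TestIntronIntron:
    def _three_intron_pm(self):
        r = np.random.default_rng(4)
        base = r.random(42)
        track1 = base + 0.01 * r.random(42)
        track2 = base + 0.01 * r.random(42)
        anti = 1.0 - base + 0.01 * r.random(42)
        pairs = pd.DataFrame({"intron_id": ["i1", "i2", "i3"],
                              "transcript_id": ["tx"] * 3})
        return _pm(np.stack([track1, track2, anti]),
                   np.tile(base, (3, 1)), pairs=pairs)

    def test_anti_tracking_intron_has_negative_max(self):
        pm = self._three_intron_pm()
        rho = timecourse_correlation(pm)
        out = intron_intron_extremes(pm, rho, top_fraction=1.0)
        anti = out.set_index("intron_id").loc["i3"]
        assert anti["max_rho"] < 0

    def test_identical_sibling_pair(self):
        r = np.random.default_rng(5)
        m = r.random(42)
        pairs = pd.DataFrame({"intron_id": ["a", "b"],
                              "transcript_id": ["tx"] * 2})
        pm = _pm(np.stack([m, m]), np.stack([m, m]), pairs=pairs)
        rho = timecourse_correlation(pm)
        out = intron_intron_extremes(pm, rho, top_fraction=1.0)
        assert np.allclose(out[["min_rho", "max_rho"]], 1.0)

    def test_low_density_transcripts_excluded(self):
        r = np.random.default_rng(6)
        pairs = pd.DataFrame({
            "intron_id": ["a", "b", "c", "d"],
            "transcript_id": ["hi", "hi", "lo", "lo"]})
        intron = np.vstack([10 * r.random((2, 42)) + 5,
                            0.01 * r.random((2, 42))])
        pm = _pm(intron, r.random((4, 42)) + 1, pairs=pairs)
        rho = timecourse_correlation(pm)
        out = intron_intron_extremes(pm, rho, top_fraction=0.5)
        assert set(out["transcript_id"]) == {"hi"}

    def test_single_intron_transcript_skipped(self):
        pairs = pd.DataFrame({"intron_id": ["a"], "transcript_id": ["tx"]})
        r = np.random.default_rng(7)
        pm = _pm(r.random((1, 42)), r.random((1, 42)), pairs=pairs)
        rho = timecourse_correlation(pm)
        assert intron_intron_extremes(pm, rho, top_fraction=1.0).empty


class TestRatios:
    def test_maxmin_ratio(self):
        pairs = pd.DataFrame({"intron_id": ["a", "b", "c"],
                              "transcript_id": ["tx"] * 3})
        # constant within timepoint; densities 2, 5, 12
        intron = np.vstack([np.full(42, v) for v in (2.0, 5.0, 12.0)])
        pm = _pm(intron, np.full((3, 42), 10.0), pairs=pairs)
        met = intron_ratio_metrics(pm)
        assert np.allclose(met.maxmin["maxmin_ratio"], 6.0)
        rel = met.pair_rel_min.set_index("intron_id")["rel_min_ratio"]
        assert rel["c"] == pytest.approx(6.0)
        assert rel["a"] == pytest.approx(1.0)

    def test_max_intron_exon_ratio_boundary(self):
        pairs = pd.DataFrame({"intron_id": ["a"], "transcript_id": ["tx"]})
        intron = np.full((1, 42), 5.0)
        exon = np.full((1, 42), 10.0)
        intron[0, 0] = 10.0   # equal to the exon in exactly one sample
        pm = _pm(intron, exon, pairs=pairs)
        met = intron_ratio_metrics(pm)
        assert met.intron_max_ratio["a"] == pytest.approx(1.0)
        table = ratio_strata_table(met.intron_max_ratio, set())
        assert table.set_index("stratum").loc[">=1", "total"] == 1

    def test_strata_percentages(self):
        ratios = pd.Series(
            np.concatenate([np.full(88, 20.0), np.full(8, 15.0)]),
            index=[f"i{k}" for k in range(96)])
        annotated = {f"i{k}" for k in range(88)}
        table = ratio_strata_table(ratios, annotated).set_index("stratum")
        assert table.loc[">10", "total"] == 96
        assert table.loc[">10", "unannotated"] == 8
        assert table.loc[">10", "pct_unannotated"] == pytest.approx(8.3)

    def test_zero_minimum_excluded(self):
        pairs = pd.DataFrame({"intron_id": ["a", "b"],
                              "transcript_id": ["tx"] * 2})
        intron = np.vstack([np.zeros(42), np.full(42, 4.0)])
        pm = _pm(intron, np.full((2, 42), 10.0), pairs=pairs)
        met = intron_ratio_metrics(pm)
        assert met.maxmin.empty


class TestCV:
    def test_constant_values_have_zero_cv(self):
        pairs = pd.DataFrame({"intron_id": ["a"], "transcript_id": ["tx"]})
        pm = _pm(np.full((1, 42), 10.0), np.full((1, 42), 10.0), pairs=pairs)
        cv = coefficient_of_variation(pm, top_fraction=1.0)
        assert np.allclose(cv.records["cv_intron"], 0.0)

    def test_sample_sd_formula(self):
        # values (1, 2, 3): sample SD 1, mean 2 -> CV 50%
        pairs = pd.DataFrame({"intron_id": ["a"], "transcript_id": ["tx"]})
        design = make_design(3, (0,))
        pm = _pm(np.array([[1.0, 2.0, 3.0]]), np.array([[4.0, 4.0, 4.0]]),
                 pairs=pairs, design=design)
        cv = coefficient_of_variation(pm, top_fraction=1.0)
        assert cv.records["cv_intron"].iloc[0] == pytest.approx(50.0)
        assert bool(cv.intron_flags["a"]) is False  # 50% > 0%

    def test_flag_requires_single_timepoint_only(self):
        pairs = pd.DataFrame({"intron_id": ["a"], "transcript_id": ["tx"]})
        design = make_design(3, (0, 3))
        intron = np.array([[5.0, 5.0, 5.0, 1.0, 5.0, 9.0]])
        exon = np.array([[4.0, 5.0, 6.0, 5.0, 5.0, 5.0]])
        pm = _pm(intron, exon, pairs=pairs, design=design)
        cv = coefficient_of_variation(pm, top_fraction=1.0)
        # tp 0: intron CV 0 <= exon CV; tp 3: intron CV large
        assert bool(cv.intron_flags["a"]) is True


class TestSimulatedSeparation:
    def test_premrna_and_standalone_separate_by_exon_rho(self, full_run):
        ds, res = full_run
        truth = ds.truth.introns.set_index("intron_id")
        rho = res.prediction_metrics["exon_rho"].dropna()
        labels = truth["class"].reindex(rho.index)
        pre = rho[labels == "premrna"]
        alone = rho[labels == "standalone"]
        # separation AUC via the rank-sum statistic
        u = stats.mannwhitneyu(pre, alone, alternative="greater").statistic
        auc = u / (len(pre) * len(alone))
        assert auc > 0.9
        hist = correlation_histogram(alone)
        low = hist.set_index("bin").loc[["rho<=0", "0<rho<0.2"], "count"].sum()
        assert low / len(alone) > 0.5

    def test_cv_decreases_with_abundance(self, full_run):
        _, res = full_run
        rec = res.cv.records.dropna(subset=["cv_intron"])
        rec = rec[rec["mean_intron"] > 0]
        r = stats.spearmanr(rec["mean_intron"], rec["cv_intron"]).statistic
        assert r < 0
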