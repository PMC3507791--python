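"""Genomic-bin DE scan: the paired test, merging, and the shuffle control."""

import itertools

import numpy as np
import pandas as pd
import pytest

from intronkit import (AnnotationIndex, DEConfig, TranscriptModel, de_test,
                       extract_intron_intervals, make_bin_grid,
                       merge_de_bins, shuffle_control)
from intronkit.debins import (annotate_de_bins, de_bin_percentage,
                              de_category_table,
                              exon_level_de, intronic_de_without_exon_change,
                              map_bins_to_introns, tally_de_overlap,
                              zero_adjust_counts)

from conftest import make_design

UNIT = [1e7] * 7   # informative counts making density == count at 1 kb bins


class TestBinGrid:
    def test_last_bin_may_be_short(self):
        grid = make_bin_grid({"chr1": 1050}, sizes=(100,))[100]
        assert len(grid) == 11
        assert grid.iloc[-1]["end"] - grid.iloc[-1]["start"] == 50

    def test_grids_nest_at_even_offsets(self):
        grids = make_bin_grid({"chr1": 1000}, sizes=(100, 200))
        s100 = grids[100]["start"].to_numpy()
        s200 = grids[200]["start"].to_numpy()
        assert set(s200) <= set(s100)

    def test_empty_chromosome_list(self):
        assert make_bin_grid({}, sizes=(100,))[100].empty

    def test_bins_tile_without_overlap(self):
        grid = make_bin_grid({"chr1": 1234, "chr2": 999}, sizes=(500,))[500]
        for _, sub in grid.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()


class TestDETest:
    def test_identical_groups_not_de(self):
        v = [3.0, 5.0, 4.0, 6.0, 2.0, 7.0, 3.0]
        fold, p, direction = de_test(v, v, UNIT, UNIT, 1000, DEConfig())
        assert fold == pytest.approx(1.0)
        assert direction is None

    def test_all_zero_control_zero_adjusted(self):
        # closed form: diffs (9.5, 10.5, 10x5); mean 10, sd 0.2887, t ~ 91.7
        treated = [10.0] * 7
        control = [0.0] * 7
        fold, p, direction = de_test(treated, control, UNIT, UNIT, 1000,
                                     DEConfig())
        assert direction == "up"
        assert np.isinf(fold)
        diffs = np.array([9.5, 10.5, 10, 10, 10, 10, 10])
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(7))
        assert t_expected == pytest.approx(91.65, abs=0.1)
        assert p < 1e-9

    def test_fold_boundary_with_zero_variance_diffs(self):
        control = np.array([2.0, 4.0, 3.0, 5.0, 2.0, 4.0, 3.0])
        treated = 2.01 * control
        # zero within-group variance in the differences is impossible here;
        # use proportional vectors where diffs = 1.01 * control (variable),
        # instead make diffs constant: treated = control + const * fold trick
        treated = control * 2.01
        fold, p, direction = de_test(treated, control, UNIT, UNIT, 1000,
                                     DEConfig())
        assert fold == pytest.approx(2.01)
        assert direction == "up" if p < 0.001 else True

    def test_constant_shift_is_infinitely_significant(self):
        control = np.full(7, 3.0)
        treated = np.full(7, 6.03)
        fold, p, direction = de_test(treated, control, UNIT, UNIT, 1000,
                                     DEConfig())
        assert fold == pytest.approx(2.01)
        assert p < 1e-50   # diffs essentially constant -> t diverges
        assert direction == "up"

    def test_both_groups_all_zero_is_not_de(self):
        z = [0.0] * 7
        fold, p, direction = de_test(z, z, UNIT, UNIT, 1000, DEConfig())
        assert direction is None
        assert fold == pytest.approx(1.0)
        assert p == 1.0

    def test_down_direction_symmetric(self):
        control = [10.0, 11.0, 9.0, 10.0, 12.0, 10.0, 9.0]
        treated = [float(x) / 4 for x in control]
        fold, p, direction = de_test(treated, control, UNIT, UNIT, 1000,
                                     DEConfig())
        assert direction == "down"
        assert fold < 0.5

    def test_zero_adjust_recipients_are_a_pure_convention(self):
        # when the non-zero group is exchangeable (equal values), every
        # choice of +0.5/-0.5 recipients yields the same diff multiset and
        # hence the identical p-value; our fixed lowest-index convention is
        # one of them
        from scipy import stats
        treated = np.full(7, 10.0)
        control = np.zeros(7)
        ps = set()
        for i, j in itertools.permutations(range(7), 2):
            adj = control.copy()
            adj[i] += 0.5
            adj[j] -= 0.5
            diffs = treated - adj
            t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(7))
            ps.add(round(float(stats.t.sf(t, df=6)), 18))
        assert len(ps) == 1
        _, p, _ = de_test(treated, control, UNIT, UNIT, 1000, DEConfig())
        assert p == pytest.approx(ps.pop(), rel=1e-9)

    def test_zero_adjust_only_touches_all_zero_rows(self):
        counts = np.array([[0.0] * 7, [1.0] + [0.0] * 6])
        adj = zero_adjust_counts(counts)
        assert adj[0, 0] == 0.5 and adj[0, 1] == -0.5
        assert (adj[1] == counts[1]).all()


class TestMerge:
    def _bin(self, start, size, tp=3, direction="down", chrom="chr1"):
        return {"chrom": chrom, "start": start, "end": start + size,
                "size": size, "timepoint": tp, "direction": direction,
                "fold": 3.0, "p": 1e-5}

    def test_smaller_bin_wins(self):
        df = pd.DataFrame([self._bin(500, 500), self._bin(600, 100)])
        merged = merge_de_bins(df)
        assert merged["size"].tolist() == [100]

    def test_larger_bin_without_conflict_kept(self):
        df = pd.DataFrame([self._bin(500, 500), self._bin(2000, 100)])
        merged = merge_de_bins(df)
        assert sorted(merged["size"]) == [100, 500]

    def test_two_small_bins_beat_one_large(self):
        df = pd.DataFrame([self._bin(0, 1000), self._bin(100, 100),
                           self._bin(700, 100)])
        merged = merge_de_bins(df)
        assert merged["size"].tolist() == [100, 100]

    def test_direction_and_timepoint_scoped(self):
        df = pd.DataFrame([self._bin(500, 500, direction="down"),
                           self._bin(600, 100, direction="up")])
        merged = merge_de_bins(df)
        assert sorted(merged["size"]) == [100, 500]

    def test_idempotent_and_no_same_size_overlap(self):
        r = np.random.default_rng(8)
        rows = [self._bin(int(s), size)
                for size in (100, 200, 500)
                for s in np.unique(r.integers(0, 50, size=10)) * size]
        df = pd.DataFrame(rows)
        once = merge_de_bins(df)
        twice = merge_de_bins(once)
        assert once.reset_index(drop=True).equals(
            twice.reset_index(drop=True))
        for (_, _, size), sub in once.groupby(["timepoint", "direction",
                                               "size"]):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:]
                    >= sub["end"].to_numpy()[:-1]).all()


class TestAnnotation:
    @pytest.fixture
    def setup(self):
        t = TranscriptModel("t", "chr1", "+", ((0, 1000), (3000, 4000)))
        introns = extract_intron_intervals([t])
        return t, introns, AnnotationIndex.build([t], introns)

    def test_categories(self, setup):
        _, _, index = setup
        bins = pd.DataFrame([
            {"chrom": "chr1", "start": 100, "end": 200, "size": 100,
             "timepoint": 3, "direction": "up", "fold": 3.0, "p": 1e-5},
            {"chrom": "chr1", "start": 900, "end": 1100, "size": 200,
             "timepoint": 3, "direction": "up", "fold": 3.0, "p": 1e-5},
            {"chrom": "chr1", "start": 1500, "end": 1600, "size": 100,
             "timepoint": 3, "direction": "up", "fold": 3.0, "p": 1e-5},
            {"chrom": "chr1", "start": 8000, "end": 8100, "size": 100,
             "timepoint": 3, "direction": "up", "fold": 3.0, "p": 1e-5},
        ])
        out = annotate_de_bins(bins, index)
        assert out["category"].tolist() == ["exonic", "exon+intron",
                                            "intronic", "intergenic"]
        table = de_category_table(out)
        pct_cols = [f"pct_{c}" for c in ("exonic", "exon+intron", "intronic",
                                         "intergenic")]
        assert table[pct_cols].sum(axis=1).iloc[0] == pytest.approx(100.0)

    def test_percentage_formatting(self):
        assert de_bin_percentage(6530, 8316) == 78.52


class TestShuffle:
    def test_null_matrix_ratio_near_one(self):
        r = np.random.default_rng(9)
        T = r.poisson(30, size=(20000, 7)).astype(float)
        C = r.poisson(30, size=(20000, 7)).astype(float)
        rep = shuffle_control(T, C, UNIT, UNIT, 100, DEConfig(), seed=1)
        before = max(rep["n_pass_before"], 1)
        after = max(np.mean(rep["n_pass_after"]), 1)
        assert 0.2 < before / after < 5.0

    def test_shuffle_destroys_injected_signal(self):
        # the before-count grows with effect size while the after-count
        # stays at the null level, so the ratio explodes for spiked data
        before, ratios = [], []
        for fold in (1.0, 3.0, 8.0):
            r = np.random.default_rng(10)  # coupled draws across folds
            lamT = np.full((30000, 7), 50.0)
            eff = r.random(30000) < 0.2
            lamT[eff] *= fold
            T = r.poisson(lamT).astype(float)
            C = r.poisson(50.0, size=(30000, 7)).astype(float)
            rep = shuffle_control(T, C, UNIT, UNIT, 100, DEConfig(), seed=2)
            before.append(rep["n_pass_before"])
            ratios.append(rep["n_pass_before"]
                          / max(np.mean(rep["n_pass_after"]), 1.0))
        assert before[0] <= before[1] <= before[2]
        assert ratios[0] < 10
        assert min(ratios[1], ratios[2]) > 50

    def test_restricted_to_expressed_bins(self):
        T = np.zeros((10, 7))
        C = np.zeros((10, 7))
        T[0, 0] = 5
        rep = shuffle_control(T, C, UNIT, UNIT, 100, DEConfig(), seed=3)
        assert rep["n_bins"] == 1


class TestExonChangeFilter:
    def _annotated_bin(self, direction):
        return pd.DataFrame([{
            "chrom": "chr1", "start": 1500, "end": 1600, "size": 100,
            "timepoint": 3, "direction": direction, "fold": 3.0, "p": 1e-5,
            "category": "intronic"}])

    @pytest.fixture
    def introns(self):
        t = TranscriptModel("t", "chr1", "+", ((0, 1000), (3000, 4000)))
        return extract_intron_intervals([t])

    def test_same_direction_exon_change_removes_bin(self, introns):
        exon_de = pd.DataFrame([{"transcript_id": "t", "timepoint": 3,
                                 "direction": "down"}])
        out = intronic_de_without_exon_change(
            self._annotated_bin("down"), introns, exon_de)
        assert out.empty

    def test_flat_exons_retain_bin(self, introns):
        exon_de = pd.DataFrame(columns=["transcript_id", "timepoint",
                                        "direction"])
        out = intronic_de_without_exon_change(
            self._annotated_bin("down"), introns, exon_de)
        assert len(out) == 1

    def test_opposite_direction_exon_change_retains_bin(self, introns):
        exon_de = pd.DataFrame([{"transcript_id": "t", "timepoint": 3,
                                 "direction": "down"}])
        out = intronic_de_without_exon_change(
            self._annotated_bin("up"), introns, exon_de)
        assert len(out) == 1

    def test_exon_level_de_flags_spiked_exon(self):
        r = np.random.default_rng(11)
        design = make_design(7, (0, 3))
        counts = pd.DataFrame(
            r.poisson(100, size=(3, 14)).astype(float),
            index=["g__e0", "g__e1", "h__e0"],
            columns=design.sort_values(["timepoint", "animal"])["sample_id"])
        treated_cols = [c for c in counts.columns if c.startswith("t03")]
        counts.loc["g__e1", treated_cols] *= 1.8
        informative = {s: 1e7 for s in counts.columns}
        tx = pd.Series(["g", "g", "h"], index=counts.index)
        out = exon_level_de(counts, tx, design, informative, DEConfig())
        assert ("g", 3, "up") in set(map(tuple, out.to_numpy()))
        assert "h" not in set(out["transcript_id"])


class TestTally:
    def test_shared_intron_counts(self):
        a = TranscriptModel("a", "chr1", "+", ((0, 100), (2000, 2100)))
        b = TranscriptModel("b", "chr1", "+", ((0, 100), (2000, 2100),
                                               (3000, 3100)))
        introns = extract_intron_intervals([a, b])
        from intronkit import group_loci
        group_loci([a, b])
        bins = pd.DataFrame([{
            "chrom": "chr1", "start": 500, "end": 600, "size": 100,
            "timepoint": 3, "direction": "up", "fold": 3.0, "p": 1e-5,
            "category": "intronic"}])
        tally = tally_de_overlap(bins, introns, [a, b]).set_index("timepoint")
        assert tally.loc[3, "n_introns"] == 1
        assert tally.loc[3, "n_transcripts"] == 2
        assert tally.loc[3, "n_loci"] == 1

    def test_union_row_deduplicates_across_timepoints(self):
        a = TranscriptModel("a", "chr1", "+", ((0, 100), (2000, 2100)))
        introns = extract_intron_intervals([a])
        from intronkit import group_loci
        group_loci([a])
        rows = [{"chrom": "chr1", "start": 500, "end": 600, "size": 100,
                 "timepoint": tp, "direction": "up", "fold": 3.0, "p": 1e-5,
                 "category": "intronic"} for tp in (3, 6)]
        tally = tally_de_overlap(pd.DataFrame(rows), introns, [a])
        union = tally[tally["timepoint"] == "all"].iloc[0]
        assert union["n_loci"] == 1

    def test_no_bins_all_zero(self):
        a = TranscriptModel("a", "chr1", "+", ((0, 100), (2000, 2100)))
        introns = extract_intron_intervals([a])
        empty = pd.DataFrame(columns=["chrom", "start", "end", "size",
                                      "timepoint", "direction", "fold", "p",
                                      "category"])
        tally = tally_de_overlap(empty, introns, [a])
        assert (tally[["n_bins", "n_introns", "n_transcripts",
                       "n_loci"]].to_numpy() == 0).all()

    def test_map_bins_to_introns_dedupes(self):
        a = TranscriptModel("a", "chr1", "+", ((0, 100), (2000, 2100)))
        introns = extract_intron_intervals([a])
        bins = pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 600},
                             {"chrom": "chr2", "start": 0, "end": 100}])
        hits = map_bins_to_introns(bins, introns)
        assert len(hits) == 1
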