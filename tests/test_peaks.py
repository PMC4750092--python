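import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcap.io_formats import FragmentSet
from methylcap.peaks import (CoverageTrack, calibrate_threshold, call_peaks,
                             count_fragments_per_peak, dedup_fragments,
                             pile_coverage, rank_sum_2group)


def fragset(rows, sample="s"):
    return FragmentSet(sample, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def brute_force_peaks(values, t, cpgs):
    """Independent per-base scanner: walk every base, accumulate runs of
    coverage >= t, then trim each run to the CpGs completely inside it."""
    peaks = []
    run_start = None
    for b in range(len(values) + 1):
        above = b < len(values) and values[b] >= t
        if above and run_start is None:
            run_start = b
        elif not above and run_start is not None:
            inside = [c for c in cpgs if c >= run_start and c + 2 <= b]
            if inside:
                peaks.append((inside[0], inside[-1] + 2, len(inside)))
            run_start = None
    return peaks


class TestDedup:
    def test_exact_location_duplicates_removed(self):
        fs = fragset([("chr1", 100, 300), ("chr1", 100, 300), ("chr1", 100, 301)])
        assert dedup_fragments(fs).total_size == 2

    def test_all_unique_unchanged(self):
        fs = fragset([("chr1", 0, 10), ("chr1", 5, 20)])
        assert dedup_fragments(fs).total_size == 2

    def test_empty_set(self):
        assert dedup_fragments(fragset([])).total_size == 0

    def test_order_independent(self):
        rows = [("chr1", 5, 20), ("chr1", 0, 10), ("chr1", 5, 20)]
        a = dedup_fragments(fragset(rows))
        b = dedup_fragments(fragset(rows[::-1]))
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestPileCoverage:
    def test_single_fragment(self):
        track = pile_coverage([fragset([("chr1", 0, 3)])], "chr1", 5)
        assert list(track.values) == [1, 1, 1, 0, 0]

    def test_two_samples_sum(self):
        a = fragset([("chr1", 0, 3)], "a")
        b = fragset([("chr1", 0, 3)], "b")
        track = pile_coverage([a, b], "chr1", 5)
        assert list(track.values) == [2, 2, 2, 0, 0]

    def test_no_fragments_zero_track(self):
        track = pile_coverage([fragset([])], "chr1", 4)
        assert list(track.values) == [0, 0, 0, 0]

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError, match="outside"):
            pile_coverage([fragset([("chr1", 0, 10)])], "chr1", 5)


class TestRankSum:
    def test_identical_groups_h_zero(self):
        h, p = rank_sum_2group([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_ties_convention(self):
        assert rank_sum_2group([1, 1, 1], [1, 1, 1]) == (0.0, 1.0)

    def test_empty_group_sentinel_not_exception(self):
        h, p = rank_sum_2group([], [1, 2])
        assert np.isnan(h) and np.isnan(p)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_kruskal(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, rng.integers(2, 30)).astype(float)
        b = rng.integers(0, 10, rng.integers(2, 30)).astype(float)
        if len(set(a) | set(b)) == 1:
            return
        h, p = rank_sum_2group(a, b)
        ref = stats.kruskal(a, b)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_separated_groups(self):
        h, _ = rank_sum_2group([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(stats.kruskal([1, 2, 3], [4, 5, 6]).statistic)


class TestCalibrate:
    def test_tie_break_to_smallest_threshold(self):
        deg = np.array([0, 0, 0, 1, 1, 1], float)
        cov = np.array([0, 0, 0, 10, 10, 10], float)
        cal = calibrate_threshold(deg, cov, range(1, 11))
        assert cal.chosen_t == 1

    def test_single_cpg_no_informative_threshold(self):
        with pytest.raises(ValueError, match="no informative threshold"):
            calibrate_threshold(np.array([0.5]), np.array([3.0]), range(1, 21))

    def test_invariant_to_cpg_ordering(self):
        rng = np.random.default_rng(1)
        deg = rng.random(200)
        cov = rng.poisson(5, 200).astype(float)
        perm = rng.permutation(200)
        a = calibrate_threshold(deg, cov, range(1, 21))
        b = calibrate_threshold(deg[perm], cov[perm], range(1, 21))
        assert a.chosen_t == b.chosen_t
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_recovers_separating_threshold(self):
        """Unmethylated capture coverage ~ Poisson(1), methylated ~
        Poisson(15): the chosen threshold lands within +-2 of the
        brute-force optimum (scipy Kruskal-Wallis scan)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            meth = rng.random(n) < 0.5
            deg = np.where(meth, rng.beta(15, 1.5, n), rng.beta(1.5, 15, n))
            cov = np.where(meth, rng.poisson(15, n), rng.poisson(1, n)).astype(float)
            cal = calibrate_threshold(deg, cov, range(1, 21))
            best_t, best_p = None, 2.0
            for t in range(1, 21):
                a, b = deg[cov >= t], deg[cov < t]
                if len(a) and len(b):
                    p = stats.kruskal(a, b).pvalue
                    if p < best_p:
                        best_p, best_t = p, t
            if abs(cal.chosen_t - best_t) <= 2:
                hits += 1
        assert hits >= 9


class TestCallPeaks:
    def test_run_trimmed_to_cpg_bounds(self):
        values = np.zeros(200, int)
        values[100:130] = 5
        peaks = call_peaks(CoverageTrack("chr1", values), 5,
                           np.array([105, 120]))
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.start, pk.end, pk.n_cpg) == (105, 122, 2)

    def test_run_without_cpg_discarded(self):
        values = np.zeros(200, int)
        values[100:130] = 5
        assert call_peaks(CoverageTrack("chr1", values), 5,
                          np.array([300])) == []

    def test_cpg_must_fit_entirely_inside_run(self):
        values = np.zeros(50, int)
        values[10:20] = 3
        # CpG at 19 has its second base at 20, outside the run
        assert call_peaks(CoverageTrack("chr1", values), 3,
                          np.array([19])) == []
        peaks = call_peaks(CoverageTrack("chr1", values), 3, np.array([18]))
        assert peaks and (peaks[0].start, peaks[0].end) == (18, 20)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(50, 1000))
        values = rng.poisson(rng.uniform(0.5, 4.0), length)
        cpgs = np.sort(rng.choice(length, size=min(length // 4, 40),
                                  replace=False))
        t = int(rng.integers(1, 6))
        got = [(p.start, p.end, p.n_cpg)
               for p in call_peaks(CoverageTrack("chr1", values), t, cpgs)]
        assert got == brute_force_peaks(values, t, cpgs)

    def test_raising_threshold_never_enlarges_peaks(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(3.0, 500)
        cpgs = np.sort(rng.choice(500, 60, replace=False))
        low = call_peaks(CoverageTrack("chr1", values), 2, cpgs)
        high = call_peaks(CoverageTrack("chr1", values), 4, cpgs)
        cover_low = set()
        for p in low:
            cover_low.update(range(p.start, p.end))
        for p in high:
            assert set(range(p.start, p.end)) <= cover_low


class TestCountFragments:
    def _peaks(self):
        from methylcap.peaks import MethylationPeak
        return [MethylationPeak("peak_1", "chr1", 150, 200, 2),
                MethylationPeak("peak_2", "chr1", 250, 260, 1)]

    def test_straddling_fragment_counts_in_both(self):
        fs = fragset([("chr1", 100, 300)])
        matrix, noise = count_fragments_per_peak({"s": fs}, self._peaks())
        assert matrix.counts.loc["peak_1", "s"] == 1
        assert matrix.counts.loc["peak_2", "s"] == 1
        assert noise["s"] == 0

    def test_non_overlapping_fragment_is_noise(self):
        fs = fragset([("chr1", 0, 50)])
        _, noise = count_fragments_per_peak({"s": fs}, self._peaks())
        assert noise["s"] == 1
        assert fs.noise_size == 1

    def test_no_peaks_everything_noise(self):
        fs = fragset([("chr1", 0, 50), ("chr1", 60, 80)])
        matrix, noise = count_fragments_per_peak({"s": fs}, [])
        assert matrix.counts.empty
        assert noise["s"] == 2

    def test_overlapping_peaks_rejected(self):
        from methylcap.peaks import MethylationPeak
        bad = [MethylationPeak("a", "chr1", 0, 100, 1),
               MethylationPeak("b", "chr1", 50, 150, 1)]
        with pytest.raises(ValueError, match="overlapping"):
            count_fragments_per_peak({"s": fragset([("chr1", 0, 10)])}, bad)

    def test_assigned_plus_noise_equals_total(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 5000, 400)
        fs = fragset([("chr1", int(s), int(s + rng.integers(50, 300)))
                      for s in starts])
        from methylcap.peaks import MethylationPeak
        peaks = [MethylationPeak(f"p{i}", "chr1", s, s + 100, 1)
                 for i, s in enumerate(range(0, 6000, 500))]
        matrix, noise = count_fragments_per_peak({"s": fs}, peaks)
        overlapping = sum(
            1 for _, row in fs.frame.iterrows()
            if any(row.start < p.end and p.start < row.end for p in peaks))
        assert overlapping + noise["s"] == fs.total_size
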