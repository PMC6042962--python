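"""Peak caller: thresholding, run length, merge semantics, planted recovery."""

import numpy as np
import pytest

from chromark import simulate as sim
from chromark.model import CoverageTrack, GenomicInterval, Peak, PeakSet
from chromark.peaks import (
    PeakCallParams,
    call_peaks,
    call_raw_peaks,
    fold_change_track,
    merge_peaks,
    normalize_pair,
)

from conftest import constant_track


def ratio_track(vec):
    return CoverageTrack("ratio", {"chr1": np.asarray(vec, dtype=float)})


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(fold_threshold=1.0), dict(min_run=0),
                   dict(merge_gap=-1), dict(pseudocount=0.0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakCallParams(**kwargs)


class TestNormalizePair:
    def test_totals_meet_at_mean(self):
        ip = constant_track(200.0, 10_000)  # total 2e6
        inp = constant_track(100.0, 10_000)  # total 1e6
        ip2, inp2 = normalize_pair(ip, inp)
        assert ip2.total_signal == pytest.approx(1.5e6)
        assert inp2.total_signal == pytest.approx(1.5e6)

    def test_equal_totals_identity(self):
        ip = constant_track(100.0, 1_000)
        ip2, inp2 = normalize_pair(ip, constant_track(100.0, 1_000))
        np.testing.assert_allclose(ip2["chr1"], ip["chr1"])

    def test_zero_total_track_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            normalize_pair(constant_track(0.0, 100), constant_track(1.0, 100))

    def test_normalization_removes_depth_and_recovers_fold(self, genome):
        """Mean-of-totals normalization cancels depth_ratio exactly; the
        in-region ratio equals fold * G / (G + (fold-1)*L) — the planted
        fold shrunk by the enriched signal's share of the IP library —
        which approaches the true fold as the planted fraction vanishes."""
        region = (GenomicInterval("chr1", 20_000, 21_000), 3.0)
        ip, inp, _ = sim.generate_coverage_pair(genome, [region], 50.0, depth_ratio=2.0)
        ip2, inp2 = normalize_pair(ip, inp)
        ratio = ip2["chr1"] / inp2["chr1"]
        G = len(ip["chr1"])
        L, fold = 1_000, 3.0
        expected = fold * G / (G + (fold - 1) * L)
        np.testing.assert_allclose(ratio[20_000:21_000], expected)
        # depth-independence: depth_ratio=1 pair gives the identical ratio
        ip_1, inp_1, _ = sim.generate_coverage_pair(genome, [region], 50.0, depth_ratio=1.0)
        ip1n, inp1n = normalize_pair(ip_1, inp_1)
        np.testing.assert_allclose(ratio, ip1n["chr1"] / inp1n["chr1"])
        assert expected == pytest.approx(fold, rel=0.05)


class TestFoldChangeTrack:
    def test_equal_tracks_give_unit_ratio(self):
        r = fold_change_track(constant_track(7.0, 100), constant_track(7.0, 100))
        np.testing.assert_array_equal(r["chr1"], 1.0)

    def test_pseudocount_protects_empty_positions(self):
        r = fold_change_track(constant_track(0.0, 10), constant_track(0.0, 10), 1.0)
        np.testing.assert_array_equal(r["chr1"], 1.0)

    def test_arithmetic(self):
        r = fold_change_track(constant_track(5.0, 10), constant_track(1.0, 10), 1.0)
        np.testing.assert_array_equal(r["chr1"], 3.0)

    def test_mismatched_chromosomes_rejected(self):
        a = CoverageTrack("a", {"chr1": np.ones(10)})
        b = CoverageTrack("b", {"chr2": np.ones(10)})
        with pytest.raises(ValueError, match="chromosomes"):
            fold_change_track(a, b)


class TestCallRawPeaks:
    def test_flat_background_yields_nothing(self):
        assert len(call_raw_peaks(ratio_track(np.ones(1000)))) == 0

    def test_qualifying_run_is_one_exact_peak(self):
        vec = np.ones(1000)
        vec[100:160] = 2.5
        (peak,) = call_raw_peaks(ratio_track(vec), 2.0, 50)
        assert (peak.interval.start, peak.interval.end) == (100, 160)
        assert peak.score == pytest.approx(2.5)

    def test_run_shorter_than_min_run_discarded(self):
        vec = np.ones(1000)
        vec[100:149] = 3.0  # 49 bases
        assert len(call_raw_peaks(ratio_track(vec), 2.0, 50)) == 0

    def test_boundary_run_of_exactly_min_run_kept(self):
        vec = np.ones(1000)
        vec[100:150] = 3.0
        assert len(call_raw_peaks(ratio_track(vec), 2.0, 50)) == 1


def peakset(*spans, chrom="chr1"):
    return PeakSet([Peak(GenomicInterval(chrom, s, e), sc) for s, e, sc in spans])


class TestMergePeaks:
    def test_gap_399_merges(self):
        merged = merge_peaks(peakset((100, 200, 2.0), (599, 700, 2.0)), 400)
        assert [(p.interval.start, p.interval.end) for p in merged] == [(100, 700)]

    def test_gap_400_does_not_merge(self):
        merged = merge_peaks(peakset((100, 200, 2.0), (600, 700, 2.0)), 400)
        assert len(merged) == 2

    def test_merged_score_is_length_weighted_mean(self):
        merged = merge_peaks(peakset((0, 100, 2.0), (150, 450, 4.0)), 400)
        assert merged[0].score == pytest.approx((2.0 * 100 + 4.0 * 300) / 400)

    def test_chain_collapses_to_fixed_point(self):
        """Peaks 300 bases apart all collapse into one; oracle is repeated
        pairwise merging until stable."""
        spans = [(i * 400, i * 400 + 100, 2.0) for i in range(10)]  # gaps of 300
        merged = merge_peaks(peakset(*spans), 400)
        assert [(p.interval.start, p.interval.end) for p in merged] == [(0, 3700)]

        # independent oracle: repeatedly merge the first mergeable pair
        intervals = [(s, e) for s, e, _ in spans]
        changed = True
        while changed:
            changed = False
            for i in range(len(intervals) - 1):
                if intervals[i + 1][0] - intervals[i][1] < 400:
                    intervals[i] = (intervals[i][0], intervals[i + 1][1])
                    del intervals[i + 1]
                    changed = True
                    break
        assert intervals == [(0, 3700)]

    def test_idempotence(self, rng):
        starts = np.cumsum(rng.integers(50, 800, size=30))
        ps = peakset(*[(int(s), int(s) + 40, 2.0) for s in starts])
        once = merge_peaks(ps, 400)
        twice = merge_peaks(once, 400)
        assert [(p.interval, p.score) for p in once] == [
            (p.interval, p.score) for p in twice
        ]

    def test_cross_chromosome_peaks_never_merge(self):
        ps = PeakSet(
            [
                Peak(GenomicInterval("chr1", 100, 200), 2.0),
                Peak(GenomicInterval("chr2", 210, 300), 2.0),
            ]
        )
        assert len(merge_peaks(ps, 400)) == 2


class TestCallPeaksEndToEnd:
    def test_only_regions_above_threshold_called_base_exact(self, genome):
        """Noiseless pair with planted folds {3, 1.5}: only the fold-3
        region is returned, base for base (1.5 < the 2-fold threshold)."""
        regions = [
            (GenomicInterval("chr1", 10_000, 10_500), 3.0),
            (GenomicInterval("chr1", 30_000, 30_500), 1.5),
        ]
        ip, inp, _ = sim.generate_coverage_pair(genome, regions, 50.0)
        peaks = call_peaks(ip, inp)
        assert [(p.interval.start, p.interval.end) for p in peaks] == [(10_000, 10_500)]

    def test_nearby_planted_regions_merge(self, genome):
        regions = [
            (GenomicInterval("chr1", 10_000, 10_500), 3.0),
            (GenomicInterval("chr1", 10_800, 11_300), 3.0),  # 300-base gap
        ]
        ip, inp, _ = sim.generate_coverage_pair(genome, regions, 50.0)
        peaks = call_peaks(ip, inp)
        assert [(p.interval.start, p.interval.end) for p in peaks] == [(10_000, 11_300)]

    def test_empty_genome_empty_peakset(self):
        ip = constant_track(50.0, 1_000)
        inp = constant_track(50.0, 1_000)
        assert len(call_peaks(ip, inp)) == 0

    def test_source_params_recorded(self, genome):
        region = [(GenomicInterval("chr1", 10_000, 10_500), 3.0)]
        ip, inp, _ = sim.generate_coverage_pair(genome, region, 50.0)
        params = PeakCallParams(fold_threshold=2.5)
        assert call_peaks(ip, inp, params).source_params["fold_threshold"] == 2.5


@pytest.fixture(scope="module")
def noisy_ratio():
    rng = np.random.default_rng(77)
    return ratio_track(rng.uniform(0.5, 3.5, size=50_000))


class TestMonotonicity:

    def test_raising_fold_threshold_never_adds_bases(self, noisy_ratio):
        covered = [
            call_raw_peaks(noisy_ratio, thr, 5).total_bases
            for thr in (1.5, 2.0, 2.5, 3.0)
        ]
        assert covered == sorted(covered, reverse=True)

    def test_raising_min_run_never_adds_bases(self, noisy_ratio):
        covered = [
            call_raw_peaks(noisy_ratio, 2.0, mr).total_bases for mr in (1, 5, 20, 50)
        ]
        assert covered == sorted(covered, reverse=True)

    def test_raising_merge_gap_never_adds_peaks(self, noisy_ratio):
        raw = call_raw_peaks(noisy_ratio, 2.0, 3)
        counts = [len(merge_peaks(raw, g)) for g in (0, 50, 200, 400, 1000)]
        assert counts == sorted(counts, reverse=True)
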