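"""Log-ratio computation, CBS segmentation and LAD calling."""

import numpy as np
import pytest

from ladscape._segment import max_arc_stat, segment_values
from ladscape.damid import (
    DamProfile,
    SegmentTrack,
    bin_track,
    call_lads,
    compute_log_ratio,
    lad_metrics,
    segment_track,
)
from ladscape.intervals import FragmentMap, GenomicInterval


def tiny_map(n=2, frag=50):
    frags = [GenomicInterval("chr1", i * frag, (i + 1) * frag) for i in range(n)]
    return FragmentMap(genome={"chr1": n * frag}, fragments=frags)


class TestLogRatio:
    def test_symmetric_input_is_zero(self):
        prof = DamProfile("c", tiny_map(), np.array([8, 8]), np.array([8, 8]))
        out = compute_log_ratio(prof, pseudocount=1.0)
        assert np.allclose(out.log_ratio, [0.0, 0.0])

    def test_hand_arithmetic(self):
        # equal totals so library scaling is the identity
        prof = DamProfile("c", tiny_map(), np.array([16, 4]), np.array([4, 16]))
        out = compute_log_ratio(prof, pseudocount=1.0)
        want = [np.log2(17 / 5), np.log2(5 / 17)]
        assert np.allclose(out.log_ratio, want)

    def test_all_zero_masked(self):
        prof = DamProfile("c", tiny_map(4, 25), np.zeros(4, int), np.zeros(4, int))
        out = compute_log_ratio(prof)
        assert out.n_masked == 4
        assert np.isnan(out.log_ratio).all()

    def test_zero_pseudocount_masks_not_inf(self):
        prof = DamProfile("c", tiny_map(), np.array([4, 0]), np.array([0, 4]))
        with pytest.warns(UserWarning, match="masked"):
            out = compute_log_ratio(prof, pseudocount=0.0, normalize="none")
        assert not np.isinf(out.log_ratio[~np.isnan(out.log_ratio)]).any()

    def test_library_size_normalization_scales_totals(self):
        prof = DamProfile("c", tiny_map(), np.array([20, 20]), np.array([10, 10]))
        out = compute_log_ratio(prof, pseudocount=0.0, normalize="library_size")
        assert np.allclose(out.log_ratio, [0.0, 0.0])


class TestBinTrack:
    def test_matches_per_base_oracle(self, rng):
        # irregular fragments, random values: bin mean must equal the
        # brute-force per-base average of the piecewise-constant track
        bounds = np.sort(rng.choice(np.arange(4, 996, 4), size=20, replace=False))
        edges = [0, *bounds.tolist(), 1000]
        frags = [GenomicInterval("chr1", s, e) for s, e in zip(edges[:-1], edges[1:])]
        fm = FragmentMap(genome={"chr1": 1000}, fragments=frags)
        vals = rng.normal(size=len(frags))
        prof = DamProfile("c", fm, np.ones(len(frags), int), np.ones(len(frags), int),
                          log_ratio=vals)
        ivs, means, _ = bin_track(prof, 128)
        base = np.empty(1000)
        for fr, v in zip(frags, vals):
            base[fr.start : fr.end] = v
        for iv, m in zip(ivs, means):
            assert m == pytest.approx(base[iv.start : iv.end].mean())

    def test_two_equal_fragments_average(self):
        fm = tiny_map(2, 50)
        prof = DamProfile("c", fm, np.ones(2, int), np.ones(2, int),
                          log_ratio=np.array([1.0, 3.0]))
        ivs, means, nfrag = bin_track(prof, 100)
        assert len(ivs) == 1 and means[0] == pytest.approx(2.0) and nfrag[0] == 2

    def test_masked_bins_dropped(self):
        fm = tiny_map(4, 50)
        lr = np.array([1.0, np.nan, np.nan, 2.0])
        prof = DamProfile("c", fm, np.ones(4, int), np.ones(4, int), log_ratio=lr)
        ivs, means, _ = bin_track(prof, 100)
        assert [iv.start for iv in ivs] == [0, 100]
        assert np.allclose(means, [1.0, 2.0])


def brute_max_arc(x, min_width):
    """Exhaustive-scan oracle for the best CBS arc."""
    x = np.asarray(x, float)
    n = len(x)
    best, bi, bj = -1.0, 0, 0
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            k = j - i
            if n - k < min_width:
                continue
            inside = x[i:j].mean()
            outside = (x.sum() - x[i:j].sum()) / (n - k)
            z = abs(inside - outside) / np.sqrt(1.0 / k + 1.0 / (n - k))
            if z > best + 1e-12:
                best, bi, bj = z, i, j
    return best, bi, bj


class TestSegmentation:
    def test_arc_scan_matches_exhaustive_oracle(self, rng):
        # an arc and its complement share the statistic and induce the
        # same cuts, so compare the cut set rather than the raw (i, j)
        for n in [5, 8, 13, 40, 200]:
            x = rng.normal(size=n)
            t, i, j = max_arc_stat(x, 2)
            tb, ib, jb = brute_max_arc(x, 2)
            assert t == pytest.approx(tb)
            assert {i, j} - {0, n} == {ib, jb} - {0, n}

    def test_constant_track_single_segment(self):
        x = np.ones(100)
        assert segment_values(x, rng=np.random.default_rng(0)) == []

    def test_noise_free_step_exact_breakpoint(self):
        x = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        breaks = segment_values(x, alpha=0.5, rng=np.random.default_rng(0))
        assert breaks == [50]

    def test_planted_three_segments_recovered(self):
        truth = [40, 80]
        means = np.concatenate([np.zeros(40), np.full(40, 1.5), np.zeros(40)])
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = means + r.normal(0, 0.2, size=120)
            breaks = segment_values(x, alpha=0.01, n_perm=400, rng=r)
            ok = len(breaks) == 2 and all(
                min(abs(b - t) for b in breaks) <= 2 for t in truth
            )
            hits += ok
        assert hits >= 95

    def test_shift_invariance(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(2, 0.3, 30)])
        b1 = segment_values(x, rng=np.random.default_rng(7))
        b2 = segment_values(x + 5.0, rng=np.random.default_rng(7))
        assert b1 == b2

    def test_determinism_for_fixed_seed(self, rng):
        ivs = [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(60)]
        vals = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(2, 0.3, 30)])
        t1 = segment_track(ivs, vals, {"chr1": 600}, seed=3)
        t2 = segment_track(ivs, vals, {"chr1": 600}, seed=3)
        assert t1.segments == t2.segments

    def test_missing_values_excluded(self):
        ivs = [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(4)]
        vals = np.array([np.nan, 1.0, 1.0, np.nan])
        tr = segment_track(ivs, vals, {"chr1": 40}, seed=0)
        assert len(tr.segments) == 1
        iv, mean, n = tr.segments[0]
        assert (iv.start, iv.end, mean, n) == (10, 30, 1.0, 2)


class TestCallLads:
    def mk_track(self, triples):
        return SegmentTrack(
            segments=[
                (GenomicInterval("chr1", s, e), m, (e - s) // 10) for s, e, m in triples
            ],
            genome={"chr1": 300_000},
        )

    def test_positive_segment_becomes_lad(self):
        tr = self.mk_track([(0, 100_000, -0.5), (100_000, 220_000, 0.8), (220_000, 300_000, -0.3)])
        ls = call_lads(tr, threshold=0.0)
        assert ls.lads == [GenomicInterval("chr1", 100_000, 220_000)]
        assert ls.metrics["genome_coverage_pct"] == pytest.approx(40.0)

    def test_all_negative_empty(self):
        tr = self.mk_track([(0, 150_000, -0.5), (150_000, 300_000, -0.1)])
        ls = call_lads(tr)
        assert ls.lads == [] and ls.metrics["genome_coverage_pct"] == 0.0

    def test_merge_gap_and_min_size(self):
        tr = self.mk_track(
            [(0, 50_000, 1.0), (50_000, 54_000, -1.0), (54_000, 100_000, 1.0),
             (200_000, 208_000, 1.0)]
        )
        ls = call_lads(tr, merge_gap=5_000, min_lad_size=10_000)
        # 4 kb dip bridged; isolated 8 kb segment dropped
        assert ls.lads == [GenomicInterval("chr1", 0, 100_000)]

    def test_metrics_median_and_inside_outside(self):
        tr = self.mk_track([(0, 40_000, 1.0), (40_000, 300_000, -1.0)])
        ls = call_lads(tr)
        ivs = [GenomicInterval("chr1", i * 10_000, (i + 1) * 10_000) for i in range(30)]
        vals = np.array([1.0] * 4 + [-1.0] * 26)
        m = lad_metrics(ls, {"chr1": 300_000}, track=(ivs, vals))
        assert m["median_size_bp"] == 40_000
        assert m["mean_log_ratio_inside"] > m["mean_log_ratio_outside"]
        with pytest.raises(ValueError, match="empty genome"):
            lad_metrics(ls, {})
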