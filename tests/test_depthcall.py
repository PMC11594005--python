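"""Caller contracts: GC correction, normalisation, exact segmentation,
copy-state calling and the strict hard filters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvpop.depthcall import (
    CnvCall,
    DepthTrack,
    GenomeLayout,
    Segment,
    call_states,
    filter_calls,
    gc_correct,
    mad_variance,
    normalize,
    segment,
    segmentation_cost,
)


def make_track(counts, gc=None, q0=None, sample="s1", w=200):
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    return DepthTrack(
        sample=sample,
        bin_width=w,
        counts={"chr1": counts},
        gc={"chr1": np.asarray(gc) if gc is not None else np.full(n, 0.5)},
        q0={"chr1": np.asarray(q0) if q0 is not None else np.full(n, 0.02)},
    )


def layout_for(track):
    return GenomeLayout(lengths={c: len(v) * track.bin_width for c, v in track.counts.items()})


class TestGcCorrect:
    def test_constant_counts_unchanged(self):
        rng = np.random.default_rng(0)
        track = make_track(np.full(2000, 7.0), gc=rng.uniform(0.3, 0.7, 2000))
        out = gc_correct(track)
        np.testing.assert_allclose(out.counts["chr1"], 7.0)

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="no coverage"):
            gc_correct(make_track(np.zeros(100)))

    def test_unbiased_track_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(10, 100_000).astype(float)
        track = make_track(counts, gc=0.5 + 0.2 * np.sin(np.arange(100_000) / 77))
        out = gc_correct(track)
        ratio = out.counts["chr1"][counts > 0] / counts[counts > 0]
        assert ((ratio > 0.95) & (ratio < 1.05)).mean() >= 0.99

    def test_sinusoidal_bias_removed(self):
        """After stratified median scaling the GC-depth correlation vanishes."""
        rng = np.random.default_rng(2)
        n = 30000
        gc = 0.5 + 0.2 * np.sin(2 * np.pi * np.arange(n) / 523)
        mu = 10.0 * (1 + 0.3 * np.sin(2 * np.pi * gc))
        track = make_track(rng.poisson(mu).astype(float), gc=gc)
        before = abs(np.corrcoef(track.counts["chr1"], gc)[0, 1])
        out = gc_correct(track)
        after = abs(np.corrcoef(out.counts["chr1"], gc)[0, 1])
        assert before > 0.2
        assert after < 0.05


class TestNormalize:
    def test_constant_counts_normalize_to_one(self):
        x = normalize(make_track(np.full(50, 13.0)))
        np.testing.assert_allclose(x["chr1"], 1.0)

    def test_two_level_signal(self):
        x = normalize(make_track([10.0] * 50 + [30.0] * 50))
        np.testing.assert_allclose(sorted(set(x["chr1"])), [0.5, 1.5])

    def test_mean_is_exactly_one(self):
        rng = np.random.default_rng(3)
        x = normalize(make_track(rng.poisson(10, 5000).astype(float)))
        assert abs(x["chr1"].mean() - 1.0) < 1e-12

    def test_unplaced_chroms_excluded_from_mean(self):
        track = make_track(np.full(100, 10.0))
        track.counts["scaffold_un"] = np.full(100, 100.0)
        track.gc["scaffold_un"] = np.full(100, 0.5)
        track.q0["scaffold_un"] = np.full(100, 0.02)
        layout = GenomeLayout(
            lengths={"chr1": 20_000, "scaffold_un": 20_000},
            placed={"chr1": True, "scaffold_un": False},
        )
        x = normalize(track, layout)
        np.testing.assert_allclose(x["chr1"], 1.0)


def brute_force_cost(x, beta):
    """Exhaustive minimum of SSE + beta * (#segments) over all partitions."""
    B = len(x)
    best = np.inf
    for mask in range(2 ** (B - 1)):
        breaks = [i + 1 for i in range(B - 1) if mask >> i & 1]
        best = min(best, segmentation_cost(x, breaks, beta))
    return best


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        segs = segment(np.full(100, 1.0), chrom="chr1")
        assert len(segs) == 1
        assert (segs[0].bin_start, segs[0].bin_end) == (0, 100)

    def test_clean_step_found_exactly(self):
        x = np.array([1.0] * 50 + [0.0] * 50)
        segs = segment(x, chrom="chr1", lam=2.0)
        assert [(s.bin_start, s.bin_end) for s in segs] == [(0, 50), (50, 100)]
        assert segs[0].mean == 1.0 and segs[1].mean == 0.0

    def test_segments_partition_the_chromosome(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1, 0.3, 500)
        segs = segment(x, chrom="chr1")
        assert segs[0].bin_start == 0 and segs[-1].bin_end == 500
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.bin_end == b.bin_start

    @given(
        st.lists(st.floats(min_value=-2, max_value=4, allow_nan=False), min_size=2, max_size=12),
        st.floats(min_value=0.05, max_value=2.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_dp_matches_exhaustive_optimum(self, xs, beta):
        """The PELT search attains the brute-force partition optimum."""
        x = np.array(xs)
        lam, sigma2 = 1.0, beta / max(np.log(len(x)), 1e-9)
        segs = segment(x, chrom="chr1", lam=lam, sigma2=sigma2)
        cost = segmentation_cost(x, [s.bin_start for s in segs[1:]], beta)
        assert cost == pytest.approx(brute_force_cost(x, beta), abs=1e-9)


class TestCallStates:
    def _one_segment_calls(self, level, nbins=20, noise=None, q0=None):
        rng = np.random.default_rng(0)
        x = np.full(nbins, level) if noise is None else level + rng.normal(0, noise, nbins)
        track = make_track(np.maximum(x * 10, 0), q0=q0)
        layout = layout_for(track)
        segs = [Segment("chr1", 0, nbins, float(np.mean(x)))]
        return call_states(segs, track, {"chr1": x}, layout)

    def test_diploid_segment_not_called(self):
        assert self._one_segment_calls(1.0) == []

    @pytest.mark.parametrize(
        "level,state", [(0.02, 0), (0.55, 1), (1.55, 3), (2.4, 4), (3.9, 4)]
    )
    def test_copy_state_rounding(self, level, state):
        calls = self._one_segment_calls(level, noise=0.05)
        assert len(calls) == 1
        assert calls[0].copy_state == state

    def test_single_bin_segment_p_value_one(self):
        calls = self._one_segment_calls(0.5, nbins=1)
        assert calls[0].p_value == 1.0

    def test_zero_variance_deleted_segment_significant(self):
        calls = self._one_segment_calls(0.0)
        assert calls[0].copy_state == 0
        assert calls[0].p_value == 0.0

    def test_adjacent_same_state_segments_merge(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([0.5 + rng.normal(0, 0.02, 30), 0.52 + rng.normal(0, 0.02, 30), np.full(40, 1.0)])
        track = make_track(np.maximum(x, 0) * 10)
        segs = [
            Segment("chr1", 0, 30, float(x[:30].mean())),
            Segment("chr1", 30, 60, float(x[30:60].mean())),
            Segment("chr1", 60, 100, 1.0),
        ]
        calls = call_states(segs, track, {"chr1": x}, layout_for(track))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (0, 12_000)

    def test_q0_is_count_weighted(self):
        x = np.full(10, 1.5)
        counts = np.array([30.0] * 5 + [0.0] * 5)
        q0 = np.array([0.1] * 5 + [0.9] * 5)
        track = make_track(counts, q0=q0)
        segs = [Segment("chr1", 0, 10, 1.5)]
        calls = call_states(segs, track, {"chr1": x}, layout_for(track))
        assert calls[0].q0_frac == pytest.approx(0.1)


class TestFilterCalls:
    layout = GenomeLayout(
        lengths={"chr1": 1_000_000, "scaffold_7": 100_000},
        placed={"chr1": True, "scaffold_7": False},
    )

    def _call(self, **kw):
        base = dict(
            sample="s", chrom="chr1", start=10_000, end=20_000,
            copy_state=0, d=0.0, p_value=1e-6, q0_frac=0.1,
        )
        base.update(kw)
        return CnvCall(**base)

    def test_passing_call_kept(self):
        assert filter_calls([self._call()], self.layout) == [self._call()]

    def test_length_exactly_1kb_removed(self):
        assert filter_calls([self._call(end=11_000)], self.layout) == []

    def test_q0_exactly_half_removed(self):
        assert filter_calls([self._call(q0_frac=0.5)], self.layout) == []

    def test_p_value_at_threshold_removed(self):
        assert filter_calls([self._call(p_value=0.001)], self.layout) == []

    def test_unplaced_scaffold_removed(self):
        assert filter_calls([self._call(chrom="scaffold_7")], self.layout) == []

    def test_filter_is_order_independent_conjunction(self):
        calls = [
            self._call(),
            self._call(end=11_000),
            self._call(q0_frac=0.5),
            self._call(start=30_000, end=45_000),
        ]
        for perm in itertools.permutations(calls):
            kept = filter_calls(list(perm), self.layout)
            assert {(c.start, c.end) for c in kept} == {(10_000, 20_000), (30_000, 45_000)}


class TestMadVariance:
    def test_matches_normal_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.5, 100_000)
        assert mad_variance(x) == pytest.approx(0.25, rel=0.05)

    def test_robust_to_outlier_block(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(1, 0.3, 10_000), np.full(500, 8.0)])
        assert mad_variance(x) == pytest.approx(0.09, rel=0.15)
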