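"""Kernel smoothing, band averaging, baseline normalization and event-aligned
group summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eeggc import (AlignedGroupTrajectory, BandTrajectory, align_logmean,
                   band_average, kernel_smooth, median_iqr_at, normalize_gc)


class FakeTensor:
    def __init__(self, values, freqs, times, pairs=None):
        self.values = values
        self.freqs = np.asarray(freqs, float)
        self.times = np.asarray(times, float)
        self.pairs = pairs or tuple(("a", f"p{i}") for i in range(values.shape[2]))


GRID = np.array([0.5] + list(range(1, 31)), dtype=float)


class TestKernelSmooth:
    def test_constant_preserved_exactly(self):
        t = np.arange(0, 400, 4.0)
        out = kernel_smooth(t, np.full_like(t, 3.7))
        assert np.allclose(out, 3.7)

    def test_single_finite_point_fills_everywhere(self):
        t = np.arange(0, 40, 4.0)
        v = np.full_like(t, np.nan)
        v[3] = 2.5
        assert np.allclose(kernel_smooth(t, v), 2.5)

    def test_step_function_plateaus(self):
        """Far from a step (4 bandwidths), the smoothed curve sits within 1%
        of each plateau."""
        t = np.arange(-600, 600, 4.0)
        v = np.where(t < 0, 1.0, 5.0)
        out = kernel_smooth(t, v, bandwidth=50.0)
        assert abs(out[np.argmin(np.abs(t + 200))] - 1.0) < 0.01
        assert abs(out[np.argmin(np.abs(t - 200))] - 5.0) < 0.01

    def test_all_missing_stays_missing(self):
        t = np.arange(0, 40, 4.0)
        out = kernel_smooth(t, np.full_like(t, np.nan))
        assert np.isnan(out).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_convexity_bounds(self, seed):
        """Nadaraya-Watson output is a convex combination: bounded by the
        input range."""
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 500, 40))
        t += np.arange(40) * 1e-6  # strictly increasing
        v = rng.uniform(-5, 5, 40)
        out = kernel_smooth(t, v)
        assert out.min() >= v.min() - 1e-9
        assert out.max() <= v.max() + 1e-9


class TestBandAverage:
    def test_constant_tensor(self):
        tensor = FakeTensor(np.full((5, 31, 2), 0.7), GRID, np.arange(5.0))
        for band in ("delta", "alpha", "beta"):
            assert np.allclose(band_average(tensor, band), 0.7)

    def test_bin_counts_per_band(self):
        values = np.arange(31, dtype=float)[None, :, None] * np.ones((4, 1, 1))
        tensor = FakeTensor(values, GRID, np.arange(4.0))
        # delta = bins {0.5, 1}; alpha = {8..14}; beta = {21..30}
        assert np.allclose(band_average(tensor, "delta"), np.mean([0, 1]))
        assert np.allclose(band_average(tensor, "alpha"), np.mean(range(8, 15)))
        assert np.allclose(band_average(tensor, "beta"), np.mean(range(21, 31)))

    def test_hand_built_vector_matches_manual_mean(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 31)
        tensor = FakeTensor(v[None, :, None], GRID, [0.0])
        manual = v[(GRID >= 8) & (GRID <= 14)].mean()
        assert band_average(tensor, "alpha")[0, 0] == pytest.approx(manual)

    def test_unknown_band_rejected(self):
        tensor = FakeTensor(np.zeros((2, 31, 1)), GRID, [0.0, 4.0])
        with pytest.raises(KeyError, match="unknown band"):
            band_average(tensor, "gamma")

    def test_missing_propagates(self):
        values = np.ones((3, 31, 1))
        values[1, 0, 0] = np.nan  # 0.5 Hz bin missing
        tensor = FakeTensor(values, GRID, np.arange(3.0))
        out = band_average(tensor, "delta")
        assert np.isnan(out[1, 0]) and np.isfinite(out[0, 0])


class TestNormalizeGC:
    times = np.arange(2, 602, 4.0)

    def test_constant_series_becomes_one(self):
        v = np.full((self.times.size, 3), 4.2)
        out, div, flagged = normalize_gc(v, self.times, infusion_start=100.0)
        assert np.allclose(out, 1.0)
        assert np.allclose(div, 4.2)
        assert not flagged.any()

    def test_divisor_is_95th_percentile_of_baseline(self):
        v = np.zeros((self.times.size, 1))
        window = (self.times >= 100.0) & (self.times < 220.0)
        rng = np.random.default_rng(1)
        base_vals = rng.uniform(1, 100, window.sum())
        v[window, 0] = base_vals
        _, div, _ = normalize_gc(v, self.times, infusion_start=100.0)
        # oracle: linear interpolation between order statistics
        srt = np.sort(base_vals)
        h = 0.95 * (srt.size - 1)
        expected = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert div[0] == pytest.approx(expected)

    def test_scale_free(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.01, 1.0, (self.times.size, 4))
        out1, *_ = normalize_gc(v, self.times, 100.0)
        out2, *_ = normalize_gc(123.4 * v, self.times, 100.0)
        assert np.allclose(out1, out2)

    def test_subject_scope_uses_global_divisor(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.01, 1.0, (self.times.size, 4))
        out, div, _ = normalize_gc(v, self.times, 100.0, scope="subject")
        assert np.ptp(div) == 0.0

    def test_zero_baseline_pair_flagged(self):
        v = np.ones((self.times.size, 2))
        v[:, 1] = 0.0
        out, _, flagged = normalize_gc(v, self.times, 100.0)
        assert flagged.tolist() == [False, True]
        assert np.isnan(out[:, 1]).all()

    def test_requires_full_baseline_window(self):
        with pytest.raises(ValueError, match="baseline window"):
            normalize_gc(np.ones((5, 1)), np.arange(2, 22, 4.0), 10.0)


def _traj(subject, values, times=None, band="delta"):
    times = np.arange(2, 2 + 4 * values.shape[0], 4.0) if times is None else times
    return BandTrajectory(subject=subject, band=band, metric="gc",
                          times=times, values=values,
                          pairs=tuple(("x", f"p{i}") for i in range(values.shape[1])))


class TestAlignLogmean:
    def test_identical_subjects_reproduce_curve(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.1, 2.0, (200, 3))
        trajs = [_traj(f"s{i}", v.copy()) for i in range(4)]
        g = align_logmean(trajs, [400.0] * 4, "LOBR", window_seconds=120.0)
        mid = np.isfinite(g.curve).all(axis=1)
        assert mid.any()
        k = np.argmin(np.abs(g.offsets - 0.0))
        t_idx = np.argmin(np.abs(trajs[0].times - 400.0))
        assert np.allclose(g.curve[k], v[t_idx])

    def test_two_subjects_geometric_mean(self):
        a = _traj("a", np.full((100, 1), 4.0))
        b = _traj("b", np.full((100, 1), 9.0))
        g = align_logmean([a, b], [200.0, 200.0], "LOBR", window_seconds=60.0)
        k = np.argmin(np.abs(g.offsets))
        assert g.curve[k, 0] == pytest.approx(6.0)  # sqrt(4 * 9)

    def test_window_truncated_not_padded(self):
        v = np.full((50, 1), 2.0)  # 200-s recording
        g = align_logmean([_traj("a", v)], [180.0], "ROBR", window_seconds=120.0)
        late = g.offsets > 25.0
        assert np.isnan(g.curve[late]).all()
        assert (g.n_subjects[late] == 0).all()
        early = np.abs(g.offsets) <= 20.0
        assert np.isfinite(g.curve[early]).all()

    def test_zero_values_floored_and_counted(self):
        v = np.full((100, 1), 1.0)
        v[40:60] = 0.0
        g = align_logmean([_traj("a", v)], [200.0], "LOBR", window_seconds=60.0)
        assert g.floor_events > 0
        assert np.nanmin(g.curve) >= 1e-12


class TestMedianIQR:
    def test_known_values(self):
        med, iqr = median_iqr_at(np.array([[1.0, 2, 3, 4, 5]]), np.array([0.0]), 0.0)
        assert med == 3.0 and iqr == 2.0

    def test_all_equal_has_zero_iqr(self):
        med, iqr = median_iqr_at(np.full((1, 9), 1.5), np.array([0.0]), 0.0)
        assert med == 1.5 and iqr == 0.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(6)
        row = rng.standard_normal(101)
        med, iqr = median_iqr_at(row[None], np.array([0.0]), 0.0)
        srt = np.sort(row)
        assert med == pytest.approx(srt[50])
        q25, q75 = np.percentile(srt, [25, 75])
        assert iqr == pytest.approx(q75 - q25)
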