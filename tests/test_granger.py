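"""Morf lattice estimation, order selection, residual gating and the Geweke
spectral decomposition."""

import numpy as np
import pytest

from eeggc import (VARSpec, analytic_spectral_gc, default_session_plan,
                   fit_var_morf, gc_over_session, durbin_watson_gate,
                   preprocess, select_order_bic, simulate_session,
                   simulate_var, spectral_gc, DEFAULT_FREQS)
from eeggc.granger import _dw_pvalues, _morf_lattice, ordered_pair_names

from conftest import stable_random_varspec
from test_synthetic import ols_var_fit

VAR3 = VARSpec(
    np.array([[[0.4, 0.2], [0.0, 0.3]],
              [[0.15, 0.0], [0.1, 0.1]],
              [[-0.1, 0.05], [0.0, -0.05]]]),
    np.array([[1.0, 0.3], [0.3, 1.2]]),
)

# Order-3 process whose lag-3 dynamics are material, so the order is
# identifiable from 4-s windows (the BIC penalty at n=500 is ~0.05 per order).
ORDER3_SPEC = VARSpec(
    np.array([[[0.35, 0.2], [0.0, 0.25]],
              [[0.0, 0.0], [0.15, 0.0]],
              [[-0.35, 0.1], [0.1, -0.3]]]),
    np.array([[1.0, 0.2], [0.2, 1.0]]),
)


class TestMorfFit:
    def test_white_noise_coefficients_small(self):
        """On white noise the fitted coefficients follow the ~1/sqrt(n)
        sampling distribution: over 500 repeated fits at n=500 fewer than 1%
        of entries exceed 0.15 (a 3.3-sigma bound), and the fitted noise
        covariance tracks the sample covariance."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((500, 2, 500))
        coeffs, sigma = _morf_lattice(x, 3)
        exceed = (np.abs(coeffs) > 0.15).mean()
        assert exceed < 0.01
        sample_cov = x @ x.transpose(0, 2, 1) / x.shape[2]
        assert np.abs(sigma - sample_cov).max() < 0.1

    def test_var3_parameter_recovery(self):
        x = simulate_var(VAR3, 20_000, seed=2)
        fit = fit_var_morf(x, order=3)
        assert np.abs(fit.coeffs - VAR3.coeffs).max() < 0.05
        assert np.abs(fit.noise_cov - VAR3.noise_cov).max() < 0.05

    def test_agrees_with_ols_on_long_series(self):
        x = simulate_var(VAR3, 30_000, seed=3)
        fit = fit_var_morf(x, order=3)
        a_ols = ols_var_fit(x, 3)
        assert np.abs(fit.coeffs - a_ols).max() < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError, match=r"\(2, n\)"):
            fit_var_morf(np.zeros((3, 100)))
        with pytest.raises(ValueError, match="order"):
            fit_var_morf(np.zeros((2, 20)), order=3)


class TestOrderSelection:
    def test_recovers_order_three(self):
        rng = np.random.default_rng(4)
        windows = np.stack([
            simulate_var(ORDER3_SPEC, 500, seed=int(rng.integers(2**31)))
            for _ in range(200)
        ])
        sel = select_order_bic(windows)
        assert sel.order == 3

    def test_white_noise_prefers_smallest_order(self):
        windows = np.random.default_rng(5).standard_normal((100, 2, 500))
        sel = select_order_bic(windows)
        assert sel.order == 1
        assert not sel.aic_has_interior_minimum or sel.aic[0] <= sel.aic.min() + 0.01


class TestDurbinWatson:
    def test_white_residuals_pass(self):
        fit = fit_var_morf(simulate_var(VAR3, 500, seed=6), order=3)
        assert np.all(np.abs(fit.dw_stat - 2.0) < 0.4)
        assert durbin_watson_gate(fit)

    def test_autocorrelated_residuals_fail(self):
        """d ~ 2(1 - r1): residuals with lag-1 autocorrelation 0.9 give
        d ~ 0.2 and are gated out."""
        rng = np.random.default_rng(7)
        n = 500
        e = np.zeros((2, n))
        innov = rng.standard_normal((2, n))
        for t in range(1, n):
            e[:, t] = 0.9 * e[:, t - 1] + innov[:, t]
        d, p = _dw_pvalues(e)
        assert np.all(np.abs(d - 2 * (1 - 0.9)) < 0.15)
        assert np.all(p < 0.05)


class TestSpectralGC:
    def test_independent_channels_zero_both_directions(self):
        spec = VARSpec(np.array([np.diag([0.5, 0.3])]), np.diag([1.0, 2.0]))
        x = simulate_var(spec, 5000, seed=8)
        fit = fit_var_morf(x, order=1)
        gc = spectral_gc(fit, DEFAULT_FREQS)
        assert gc.shape == (31, 2)
        assert gc.max() < 0.01  # only sampling-level bias remains

    def test_matches_analytic_oracle_on_long_series(self):
        x = simulate_var(VAR3, 30_000, seed=9)
        fit = fit_var_morf(x, order=3)
        est = spectral_gc(fit, DEFAULT_FREQS)
        truth = analytic_spectral_gc(VAR3, DEFAULT_FREQS)
        assert np.abs(est - truth).max() < 0.05

    def test_scale_invariance(self):
        x = simulate_var(VAR3, 2000, seed=10)
        g1 = spectral_gc(fit_var_morf(x, 3), DEFAULT_FREQS)
        x2 = x * np.array([[10.0], [0.2]])
        g2 = spectral_gc(fit_var_morf(x2, 3), DEFAULT_FREQS)
        assert np.abs(g1 - g2).max() < 1e-6

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            spec = stable_random_varspec(rng)
            fit = fit_var_morf(simulate_var(spec, 1000, seed=seed), 3)
            assert spectral_gc(fit, DEFAULT_FREQS).min() >= 0.0

    def test_frequencies_must_be_inside_nyquist(self):
        fit = fit_var_morf(simulate_var(VAR3, 1000, seed=13), 3)
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_gc(fit, np.array([70.0]))



@pytest.fixture(scope="module")
def single_edge_tensor():
    from dataclasses import replace

    plan = default_session_plan(seed=21, duration="short",
                                artifact_rate=0.0)
    plan = replace(plan, coupling_awake=(("F7", "Cz", 0.45),),
                   coupling_unresponsive=())
    rec, _ = simulate_session(plan)
    _, grid = preprocess(rec)
    tensor = gc_over_session(grid)
    return tensor, rec.events


class TestSessionScan:

    def test_pair_index_has_930_ordered_pairs(self, single_edge_tensor):
        tensor, _ = single_edge_tensor
        assert tensor.n_pairs == 930
        assert len(set(tensor.pairs)) == 930
        assert ("F7", "Cz") in tensor.pairs and ("Cz", "F7") in tensor.pairs

    def test_direction_and_state_contrast(self, single_edge_tensor):
        """With a single F7->Cz edge active while responsive, the responsive
        median GC(F7->Cz) beats both the reverse direction and the
        unresponsive-phase value."""
        tensor, events = single_edge_tensor
        delta = tensor.values[:, :2, :].mean(axis=1)
        fwd = tensor.pair_index("F7", "Cz")
        rev = tensor.pair_index("Cz", "F7")
        resp = tensor.times < events.lobr - 10
        unresp = (tensor.times > events.lobr + 10) & (tensor.times < events.robr - 10)
        assert (np.nanmedian(delta[resp, fwd])
                > 3 * np.nanmedian(delta[resp, rev]))
        assert (np.nanmedian(delta[resp, fwd])
                > 3 * np.nanmedian(delta[unresp, fwd]))

    def test_invalid_channel_propagates_to_all_its_pairs(self, montage31):
        from eeggc import EventTimeline, Recording, segment_and_reject

        x = np.random.default_rng(14).standard_normal((31, 1000))
        x[4, 50] = 500.0
        rec = Recording(signal=x, sample_rate=125.0, montage=montage31,
                        events=EventTimeline())
        grid = segment_and_reject(rec)
        tensor = gc_over_session(grid, freqs=np.array([10.0]))
        bad = montage31.names[4]
        for k, (src, tgt) in enumerate(tensor.pairs):
            if bad in (src, tgt):
                assert np.isnan(tensor.values[0, 0, k])
                assert not tensor.validity[0, k]
            else:
                assert tensor.validity[0, k]
        assert tensor.validity[1].all()

    def test_missing_stored_as_nan_never_zero(self, single_edge_tensor):
        tensor, _ = single_edge_tensor
        by_pair = tensor.values.transpose(0, 2, 1)  # seg x pair x freq
        assert np.isnan(by_pair[~tensor.validity]).all()

    def test_chunking_does_not_change_results(self, montage31):
        from eeggc import EventTimeline, Recording, segment_and_reject

        x = np.random.default_rng(15).standard_normal((31, 2000))
        rec = Recording(signal=x, sample_rate=125.0, montage=montage31,
                        events=EventTimeline())
        grid = segment_and_reject(rec)
        t1 = gc_over_session(grid, freqs=np.array([5.0]), segment_chunk=1)
        t2 = gc_over_session(grid, freqs=np.array([5.0]), segment_chunk=64)
        assert np.allclose(t1.values, t2.values, equal_nan=True)


def test_ordered_pair_names_layout():
    pairs = ordered_pair_names(["a", "b", "c"])
    assert pairs == (("a", "b"), ("a", "c"), ("b", "c"),
                     ("b", "a"), ("c", "a"), ("c", "b"))
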