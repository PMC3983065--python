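"""Subset construction, objective machinery, CMA-ES, cross-validation."""

import numpy as np
import pytest

from threshfit import (FitConfig, FittedTrace, ThresholdModelParams,
                       VoltageTrace, cross_validate, fit_threshold_model,
                       make_subsets, predict_spikes)
from threshfit.cmaes import cma_minimize
from threshfit.fitting import (_initial_guess, _prepare_data, _search_bounds,
                               _subset_gamma)
from threshfit import _kernels
from threshfit.model import integrate_threshold


def _fitted(n_spikes, mean_v, seed=0, duration=2000.0, dt=0.1):
    rng = np.random.default_rng(seed)
    n = int(duration / dt)
    trace = VoltageTrace(mean_v + rng.standard_normal(n), dt=dt)
    times = np.sort(rng.choice(n - 10, size=n_spikes, replace=False)) * dt
    return FittedTrace(trace=trace, rec_times=times)


class TestMakeSubsets:
    def test_protocol_mode_groups_by_tag(self):
        fts = []
        for tag in ("ITD", "IID", "ITD"):
            ft = _fitted(30, -65, seed=len(fts))
            ft.trace.meta["protocol"] = tag
            fts.append(ft)
        subsets = make_subsets(fts, mode="protocol")
        assert len(subsets) == 2
        assert {s.subset_id for s in subsets} == {"protocol:ITD", "protocol:IID"}

    def test_mean_vm_accumulates_to_min_spikes(self):
        # 6 traces of 30 spikes: subsets of 4 traces (120) + trailing 2 merged
        fts = [_fitted(30, -70 + i, seed=i) for i in range(6)]
        subsets = make_subsets(fts, mode="mean_vm")
        assert len(subsets) == 1 or all(s.n_spikes >= 120 for s in subsets)
        assert sum(len(s.member_indices) for s in subsets) == 6

    def test_240_spikes_over_8_traces_gives_2_subsets(self):
        fts = [_fitted(30, -70 + 0.5 * i, seed=10 + i) for i in range(8)]
        subsets = make_subsets(fts, mode="mean_vm")
        assert len(subsets) == 2
        assert all(s.n_spikes == 120 for s in subsets)

    def test_subsets_ordered_by_mean_voltage(self):
        fts = [_fitted(60, v, seed=i) for i, v in enumerate((-60, -72, -66, -78))]
        subsets = make_subsets(fts, mode="mean_vm")
        means = [s.mean_V for s in subsets]
        assert means == sorted(means)

    def test_too_few_spikes_single_subset_with_warning(self):
        fts = [_fitted(10, -65, seed=1)]
        with pytest.warns(UserWarning):
            subsets = make_subsets(fts, mode="mean_vm")
        assert len(subsets) == 1


class TestKernelEquivalence:
    def test_compiled_predictor_matches_reference(self, rectified_params,
                                                  ou_trace):
        """Fused numba kernel vs the numpy/scipy reference path."""
        shifted = VoltageTrace(ou_trace.samples + 6.0, dt=ou_trace.dt)
        train, theta = predict_spikes(rectified_params, shifted)
        p = rectified_params
        idx = _kernels.predict_spike_indices(
            np.ascontiguousarray(shifted.samples), shifted.dt, p.tau_theta,
            p.V_i, p.theta_offset, p.alpha, p.beta, p.k_a, 0.5)
        assert np.allclose(idx * shifted.dt, train.times)

    def test_tabled_predictor_matches_reference(self, rectified_params,
                                                ou_trace):
        shifted = VoltageTrace(ou_trace.samples + 6.0, dt=ou_trace.dt)
        train, _ = predict_spikes(rectified_params, shifted)
        ft = FittedTrace(trace=shifted, rec_times=train.times)
        traces, grid, inv_dv = _prepare_data([ft])
        from threshfit.model import steady_state_threshold
        table = np.asarray(steady_state_threshold(rectified_params, grid))
        idx = _kernels.predict_spike_indices_tabled(
            traces[0][0], shifted.dt, rectified_params.tau_theta, 0.5,
            grid[0], inv_dv, table)
        assert np.allclose(idx * shifted.dt, train.times)


class TestCmaes:
    def test_minimizes_shifted_sphere(self):
        target = np.array([0.3, -1.2, 2.5])
        res = cma_minimize(lambda x: float(np.sum((x - target) ** 2)),
                           bounds=[(-5, 5)] * 3, seed=1, popsize=10,
                           max_evals=2000)
        assert np.allclose(res.x, target, atol=1e-3)

    def test_deterministic_given_seed(self):
        fun = lambda x: float(np.sum(x ** 2) + np.sin(5 * x).sum())
        r1 = cma_minimize(fun, [(-3, 3)] * 4, seed=7, max_evals=600)
        r2 = cma_minimize(fun, [(-3, 3)] * 4, seed=7, max_evals=600)
        assert np.array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun

    def test_respects_bounds(self):
        res = cma_minimize(lambda x: float(-x[0]), [(0, 2)], seed=3,
                           max_evals=400)
        assert 0 <= res.x[0] <= 2
        assert res.fun == pytest.approx(-2.0, abs=1e-3)

    def test_f_target_stops_early(self):
        res = cma_minimize(lambda x: float(np.sum(x ** 2)), [(-5, 5)] * 3,
                           seed=2, max_evals=5000, f_target=0.5)
        assert res.fun <= 0.5
        assert res.n_evals < 5000


class TestObjective:
    def test_perfect_params_score_one_on_own_prediction(self, rectified_params,
                                                        ou_trace):
        """Gamma of a model against its own prediction is exactly 1."""
        shifted = VoltageTrace(ou_trace.samples + 6.0, dt=ou_trace.dt)
        train, _ = predict_spikes(rectified_params, shifted)
        assert len(train) > 5
        ft = FittedTrace(trace=shifted, rec_times=train.times)
        data = _prepare_data([ft])
        p = rectified_params
        x = np.array([np.log10(p.tau_theta), p.V_i, p.theta_offset,
                      p.alpha, p.beta, p.k_a])
        assert _subset_gamma(x, data, FitConfig()) == pytest.approx(1.0)

    def test_beta_below_alpha_penalized(self, ou_trace):
        ft = FittedTrace(trace=ou_trace, rec_times=np.array([100.0, 200.0]))
        data = _prepare_data([ft])
        x = np.array([0.0, -59, -57, 0.8, 0.2, 3.0])
        assert _subset_gamma(x, data, FitConfig()) < -1.0

    def test_initial_guess_inside_bounds(self, eif_fixture):
        ft = FittedTrace.from_trace(eif_fixture["trace"])
        from threshfit.fitting import DEFAULT_BOUNDS
        x0 = _initial_guess([ft], DEFAULT_BOUNDS)
        for v, (lo, hi) in zip(x0, _search_bounds(DEFAULT_BOUNDS)):
            assert lo <= v <= hi


class TestFitValidation:
    def test_too_few_spikes_rejected(self, ou_trace):
        ft = FittedTrace(trace=ou_trace, rec_times=np.array([100.0, 200.0]))
        with pytest.raises(ValueError, match="spikes"):
            fit_threshold_model([ft])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold_model([])


class TestCrossValidate:
    def test_training_subset_reproduces_training_gamma(self, rectified_params,
                                                       ou_trace):
        shifted = VoltageTrace(ou_trace.samples + 6.0, dt=ou_trace.dt)
        train, theta = predict_spikes(rectified_params, shifted)
        ft = FittedTrace(trace=shifted, rec_times=train.times)
        rows = cross_validate(rectified_params, [[ft]])
        assert rows[0]["gamma"] == pytest.approx(1.0)
        assert rows[0]["fa_percent"] == pytest.approx(0.0)

    def test_random_params_near_chance(self, eif_fixture):
        """An unfitted model is a negative control: gamma near zero."""
        ft = FittedTrace.from_trace(eif_fixture["trace"])
        wrong = ThresholdModelParams(tau_theta=10.0, V_i=-45.0,
                                     theta_offset=-45.0, alpha=0.9, beta=1.9,
                                     k_a=15.0)
        rows = cross_validate(wrong, [[ft]])
        assert rows[0]["gamma"] < 0.2
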