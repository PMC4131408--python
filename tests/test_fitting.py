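"""Staged regression, grid search, threshold selection and GLM ascent."""

import numpy as np
import pytest

from adgif.fitting import (NonlinearGrid, RankDeficientError,
                           default_threshold_grid, estimate_derivative,
                           fit_dendritic_linear, fit_glm, fit_somatic,
                           fit_twocompartment, glm_log_likelihood,
                           grid_search_dendritic)
from adgif.glm import GLMParams, sample_spikes
from adgif.kernels import Kernel, RectBasis
from adgif.model import simulate
from adgif.protocol import RecordingSet, ou_current

TRUE_NL = {"tau_m": 6.7, "d_m": 5.5, "e_m": -0.6, "tau_x": 49.9}


class TestEstimateDerivative:
    def test_linear_ramp(self):
        dt = 0.1
        v = 3.0 * np.arange(100) * dt
        np.testing.assert_allclose(estimate_derivative(v, dt), 3.0)

    def test_constant(self):
        assert np.all(estimate_derivative(np.full(50, -70.0), 0.1) == 0.0)

    def test_leaky_integrator_charging_curve(self):
        # V(t) = E + (I/g)(1 - exp(-t g/C)): first difference ~ derivative
        g, c, i, e = 22.0, 379.0, 200.0, -73.0
        dt = 0.01
        t = np.arange(20000) * dt
        v = e + (i / g) * (1.0 - np.exp(-t * g / c))
        est = estimate_derivative(v, dt)
        exact = (i / c) * np.exp(-t[:-1] * g / c)
        np.testing.assert_allclose(est, exact, rtol=1e-3)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            estimate_derivative(np.array([1.0]), 0.1)


class TestDendriticRecovery:
    def test_noiseless_recovery_exact(self, short_recording, ground_truth):
        params, mse = fit_dendritic_linear(short_recording, TRUE_NL)
        d = ground_truth.dendrite
        assert mse < 1e-8
        for got, want in [(params.c_d, d.c_d), (params.g_d, d.g_d),
                          (params.e_d, d.e_d), (params.g1, d.g1),
                          (params.g2, d.g2)]:
            assert abs(got - want) / abs(want) < 1e-6
        np.testing.assert_allclose(params.i_bap.amplitudes,
                                   d.i_bap.amplitudes, atol=1e-6)
        np.testing.assert_allclose(params.eps_sd.amplitudes,
                                   d.eps_sd.amplitudes, atol=1e-9)

    def test_measurement_noise_keeps_recovery_close(self, short_recording,
                                                    ground_truth):
        rng = np.random.default_rng(17)
        noisy = RecordingSet(
            short_recording.dt, short_recording.i_s, short_recording.i_d,
            [short_recording.v_s[0]],
            [short_recording.v_d[0] + rng.normal(0, 0.05,
                                                 short_recording.v_d[0].size)],
            [short_recording.spike_times[0]],
            split_ms=short_recording.split_ms)
        params, _ = fit_dendritic_linear(noisy, TRUE_NL)
        # white measurement noise inflates the derivative variance but
        # leaves the regression essentially unbiased
        assert abs(params.c_d - ground_truth.dendrite.c_d) / 86.0 < 0.05
        assert abs(params.g1 - ground_truth.dendrite.g1) / 567.0 < 0.25

    def test_constant_voltage_is_rank_deficient(self, short_recording):
        n = short_recording.i_s.size
        flat = RecordingSet(
            short_recording.dt, short_recording.i_s, short_recording.i_d,
            [short_recording.v_s[0]], [np.full(n, -53.0)],
            [short_recording.spike_times[0]],
            split_ms=short_recording.split_ms)
        with pytest.raises(RankDeficientError, match="V_d|const"):
            fit_dendritic_linear(flat, TRUE_NL)


class TestGridSearch:
    def test_grid_containing_truth_wins(self, short_recording):
        grid = NonlinearGrid({
            "tau_m": [4.0, 6.7, 10.0],
            "d_m": [3.5, 5.5, 8.0],
            "e_m": [-5.0, -0.6],
            "tau_x": [35.0, 49.9, 70.0],
        })
        res = grid_search_dendritic(short_recording, grid)
        assert res.diagnostics["winner"] == TRUE_NL
        assert res.train_mse_dvd < 1e-12
        assert len(res.grid_trace) == grid.size

    def test_single_point_grid(self, short_recording):
        grid = NonlinearGrid({"tau_m": [6.7], "d_m": [5.5], "e_m": [-0.6],
                              "tau_x": [49.9]})
        res = grid_search_dendritic(short_recording, grid)
        direct, mse = fit_dendritic_linear(short_recording, TRUE_NL)
        assert res.train_mse_dvd == mse
        assert res.model.c_d == direct.c_d

    def test_trace_is_recomputable(self, short_recording):
        grid = NonlinearGrid({"tau_m": [4.0, 6.7], "d_m": [5.5], "e_m": [-0.6],
                              "tau_x": [49.9]})
        res = grid_search_dendritic(short_recording, grid)
        row = res.grid_trace.iloc[0]
        _, mse = fit_dendritic_linear(
            short_recording, {k: row[k] for k in TRUE_NL})
        np.testing.assert_allclose(row["mse"], mse, rtol=1e-9)


class TestSomaticStage:
    def test_noiseless_recovery(self, short_recording, ground_truth):
        dend, _ = fit_dendritic_linear(short_recording, TRUE_NL)
        res = fit_somatic(short_recording, dend)
        s = res.model.soma
        truth = ground_truth.soma
        for got, want in [(s.c_s, truth.c_s), (s.g_s, truth.g_s),
                          (s.e_s, truth.e_s), (s.alpha, truth.alpha)]:
            assert abs(got - want) / abs(want) < 1e-6
        np.testing.assert_allclose(s.i_a.amplitudes, truth.i_a.amplitudes,
                                   atol=1e-6)
        # the true threshold point is on the default grid and must win
        assert res.diagnostics["winner"] == {"d_t": 2.0, "tau_t": 27.0,
                                             "e_t": -53.0}
        assert res.gamma_train == pytest.approx(1.0)

    def test_static_threshold_no_better_than_true(self, short_recording):
        dend, _ = fit_dendritic_linear(short_recording, TRUE_NL)
        static = fit_somatic(short_recording, dend,
                             grid=NonlinearGrid({"d_t": [0.0],
                                                 "tau_t": [27.0],
                                                 "e_t": [-53.0]}))
        moving = fit_somatic(short_recording, dend)
        assert static.gamma_train <= moving.gamma_train

    def test_no_spikes_errors_in_gamma_stage(self, ground_truth):
        # subthreshold-only recording: regression input exists, Gamma cannot
        dt = 0.1
        i_s = ou_current(0.0, 80.0, 3.0, 5000.0, dt, 21)
        i_d = ou_current(0.0, 80.0, 3.0, 5000.0, dt, 22)
        tr = simulate(ground_truth, i_s, i_d, dt)
        assert tr.n_spikes == 0
        rec = RecordingSet(dt, i_s, i_d, [tr.v_s], [tr.v_d],
                           [tr.spike_times], split_ms=5000.0)
        dend, _ = fit_dendritic_linear(rec, TRUE_NL)
        with pytest.raises(ValueError, match="no reference spikes"):
            fit_somatic(rec, dend)


def test_full_staged_fit_reproduces_spike_times(short_recording, ground_truth):
    grid = NonlinearGrid({"tau_m": [6.7], "d_m": [5.5], "e_m": [-0.6],
                          "tau_x": [49.9, 70.0]})
    res = fit_twocompartment(short_recording, dend_grid=grid)
    assert res.gamma_train == pytest.approx(1.0, abs=1e-9)
    assert res.model.dendrite.tau_x == 49.9


class TestRegressionOracle:
    def test_normal_equations_match_lstsq(self):
        # the scaled normal-equations path equals a direct least squares
        rng = np.random.default_rng(23)
        x = rng.standard_normal((200, 5)) * np.array([1, 10, 100, 0.1, 1.0])
        w_true = rng.standard_normal(5)
        y = x @ w_true
        from adgif.fitting import _solve_scaled
        w, _ = _solve_scaled(x.T @ x, x.T @ y, [f"c{i}" for i in range(5)])
        w_ref = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(w, w_ref, rtol=1e-8)


class TestFitGLM:
    def make_recording(self, params, duration=60000.0, seed=31):
        dt = 0.1
        i_s = ou_current(0.0, 200.0, 3.0, duration, dt, seed)
        i_d = ou_current(0.0, 200.0, 3.0, duration, dt, seed + 1)
        spikes = sample_spikes(params, i_s, i_d, dt, seed=seed + 2)
        n = i_s.size
        zeros = np.zeros(n)
        return RecordingSet(dt, i_s, i_d, [zeros], [zeros], [spikes],
                            split_ms=duration)

    def test_homogeneous_poisson_recovers_rate(self):
        truth = GLMParams(log_lambda0=np.log(0.015))
        rec = self.make_recording(truth)
        res = fit_glm(rec)
        fitted_rate = np.exp(res.model.log_lambda0)
        empirical = len(rec.spike_times[0]) / rec.duration_ms
        # with zero-mean inputs the fitted baseline sits at the empirical rate
        assert abs(fitted_rate - empirical) / empirical < 0.05
        assert res.diagnostics["converged"]

    def test_objective_monotone_nonincreasing(self):
        truth = GLMParams(
            log_lambda0=np.log(0.01),
            kappa_s=Kernel(RectBasis([0.0, 5.0]), [0.003]),
            eta_a=Kernel(RectBasis([0.0, 10.0]), [-2.0]))
        rec = self.make_recording(truth, seed=41)
        res = fit_glm(rec)
        trace = res.diagnostics["nll_trace"]
        assert len(trace) > 2
        assert all(trace[i + 1] <= trace[i] + 1e-7
                   for i in range(len(trace) - 1))

    def test_fit_improves_on_init(self):
        truth = GLMParams(
            log_lambda0=np.log(0.01),
            kappa_s=Kernel(RectBasis([0.0, 5.0]), [0.003]),
            eta_a=Kernel(RectBasis([0.0, 10.0]), [-2.0]))
        rec = self.make_recording(truth, seed=51)
        res = fit_glm(rec)
        ll_fit = res.diagnostics["log_likelihood"]
        baseline = GLMParams(
            log_lambda0=np.log(len(rec.spike_times[0]) / rec.duration_ms))
        assert ll_fit > glm_log_likelihood(baseline, rec, "train")

    def test_no_spikes_error(self, ground_truth):
        n = 10000
        zeros = np.zeros(n)
        rec = RecordingSet(0.1, zeros, zeros, [zeros], [zeros],
                           [np.empty(0)], split_ms=1000.0)
        with pytest.raises(ValueError):
            fit_glm(rec)
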