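"""Waveform preparation, the weighted cost, goodness-of-fit, and the
bounded multi-start least-squares fit."""

import numpy as np
import pytest

from rvcirc.calibrate import (
    WaveformSeries,
    cost,
    calibrate,
    prepare_data,
    r_squared,
    residuals,
    W_STATIC,
)
from rvcirc.model import INFLUENTIAL_ORDER, simulate


def series(t, v, kind="pressure", T=1.0):
    return WaveformSeries(t=np.asarray(t, float), v=np.asarray(v, float),
                         kind=kind, T=T)


def uniform(n, T=1.0):
    return np.arange(n) * (T / n)


class TestWaveformSeries:
    def test_validation(self):
        t = uniform(30)
        with pytest.raises(ValueError):
            series(t[:10], np.ones(10))             # too few samples
        with pytest.raises(ValueError):
            series(t[::-1], np.ones(30))            # non-monotone
        with pytest.raises(ValueError):
            series(t, -np.ones(30))                 # non-positive maximum
        with pytest.raises(ValueError):
            series(t, np.ones(30), kind="velocity")

    def test_periodic_resample(self):
        t = uniform(50)
        w = series(t, np.sin(2 * np.pi * t))
        t2 = uniform(100)
        np.testing.assert_allclose(w.resample(t2)[::2], w.v, atol=1e-12)


class TestPrepareData:
    def test_idempotent_on_matching_grid(self):
        t = uniform(100)
        p = series(t, 20 + 10 * np.sin(2 * np.pi * t))
        q = series(t, np.maximum(0, 200 * np.sin(2 * np.pi * t)), kind="flow")
        d = prepare_data(p, q, Nt=100)
        np.testing.assert_allclose(d.pressure, p.v, atol=1e-9)
        np.testing.assert_allclose(d.flow, q.v, atol=1e-9)

    def test_constant_series_anchor_equals_constant(self):
        t = uniform(40)
        d = prepare_data(series(t, np.full(40, 7.0)),
                         series(t, np.full(40, 3.0), kind="flow"), Nt=40)
        assert d.p_min == pytest.approx(7.0)
        assert d.p_max == pytest.approx(7.0)
        assert d.q_max == pytest.approx(3.0)

    def test_linear_interpolation_error_bound(self):
        # resampling a sawtooth at doubled density stays within the
        # classical h^2/8 * max|f''| bound (here piecewise linear: error
        # bounded by half the grid step times the slope)
        t = uniform(64)
        saw = 2 * np.abs((t % 0.5) - 0.25)
        w = series(t, saw + 1.0)
        t2 = uniform(128)
        err = np.abs(w.resample(t2) - (2 * np.abs((t2 % 0.5) - 0.25) + 1.0))
        slope = 4.0
        assert err.max() <= 0.5 * (1 / 64) * slope + 1e-12

    def test_cycle_length_mismatch_rejected(self):
        t = uniform(40)
        p = series(t, np.ones(40) + t)
        q = series(uniform(40, T=1.1) , np.ones(40), kind="flow", T=1.1)
        with pytest.raises(ValueError):
            prepare_data(p, q)


class TestCost:
    def test_zero_at_generating_parameters(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_true, pt.flow_true, Nt=100)
        J = cost(pt.truth.theta(), d, pt.truth,
                 sim_kwargs={"stop_tol": 1e-7})
        assert J < 1e-10

    def test_static_term_arithmetic(self, virtual_patient):
        # scaling the whole model output by 1.1 shifts every static anchor
        # by 10%, contributing W_S * 0.01 per anchor term
        pt = virtual_patient
        d = prepare_data(pt.pressure_true, pt.flow_true, Nt=100)
        P, Q = d.pressure, d.flow
        from rvcirc.calibrate import _residual_vector
        r = _residual_vector(1.1 * P, Q, d)
        static_p = r[-3:-1]
        expected_min = W_STATIC * (0.1 * d.p_min / max(d.p_min, 1.0)) ** 2
        assert static_p[0] ** 2 == pytest.approx(expected_min, rel=1e-6)
        assert static_p[1] ** 2 == pytest.approx(W_STATIC * 0.01, rel=1e-6)

    def test_dynamic_weight_normalization(self, virtual_patient):
        # doubling the sampling density leaves the dynamic cost unchanged
        # in expectation: each term carries weight 1/Nt
        pt = virtual_patient
        from rvcirc.calibrate import _residual_vector
        offsets = {}
        for Nt in (50, 100):
            d = prepare_data(pt.pressure_true, pt.flow_true, Nt=Nt)
            r = _residual_vector(d.pressure * 1.02, d.flow, d)
            offsets[Nt] = np.sum(r[:Nt] ** 2)
        assert offsets[50] == pytest.approx(offsets[100], rel=0.02)

    def test_cost_equals_sum_of_squared_residuals(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_obs, pt.flow_obs, Nt=80)
        theta = pt.truth.theta() * 1.05
        kw = {"stop_tol": 1e-5}
        r = residuals(theta, d, pt.truth, INFLUENTIAL_ORDER, kw)
        assert cost(theta, d, pt.truth, INFLUENTIAL_ORDER, kw) == \
            pytest.approx(float(r @ r), rel=1e-12)

    def test_failed_simulation_penalty(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_true, pt.flow_true, Nt=50)
        bad = pt.truth.theta().copy()
        bad[INFLUENTIAL_ORDER.index("tmax")] = 2 * pt.truth.T  # invalid timing
        assert cost(bad, d, pt.truth) == pytest.approx(1e6)


class TestRSquared:
    def test_identical_traces(self):
        x = np.array([1.0, 2.0, 5.0])
        assert r_squared(x, x) == pytest.approx(1.0)

    def test_mean_model_scores_zero(self):
        data = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(np.full(4, data.mean()), data) == pytest.approx(0.0)

    def test_three_point_arithmetic(self):
        assert r_squared(np.array([1.0, 2.0, 4.0]),
                         np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.ones(5))


class TestCalibrate:
    def test_perfect_start_converges_immediately(self, virtual_patient):
        # data on the patient's native grid so the model can match exactly
        pt = virtual_patient
        d = prepare_data(pt.pressure_true, pt.flow_true, Nt=100)
        res = calibrate(d, pt.truth, n_starts=1, seed=0, max_nfev=40,
                        sim_kwargs={"stop_tol": 1e-7})
        assert res.cost < 1e-8
        assert res.r2_pressure > 0.9999
        assert res.r2_flow > 0.9999

    def test_never_worse_than_start_and_within_bounds(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_obs, pt.flow_obs, Nt=60)
        theta0 = pt.truth.theta() * 1.1
        from rvcirc.initialize import build_bounds
        b = build_bounds(pt.truth)
        theta0 = b.clip(theta0)
        J0 = cost(theta0, d, pt.truth, sim_kwargs={"stop_tol": 1e-4})
        res = calibrate(d, pt.truth, theta0=theta0, n_starts=2, seed=3,
                        max_nfev=60)
        assert res.cost <= J0 + 1e-12
        assert b.contains(res.theta)
        assert res.cost == pytest.approx(res.starts["cost"].min())

    def test_deterministic_under_seed(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_obs, pt.flow_obs, Nt=50)
        kw = dict(n_starts=2, max_nfev=25)
        r1 = calibrate(d, pt.truth, seed=7, **kw)
        r2 = calibrate(d, pt.truth, seed=7, **kw)
        np.testing.assert_array_equal(r1.theta, r2.theta)
        assert r1.cost == r2.cost
        # different seed draws different perturbed starts
        r3 = calibrate(d, pt.truth, seed=8, **kw)
        assert not np.array_equal(
            r1.starts.filter(like="x0_").iloc[1].to_numpy(),
            r3.starts.filter(like="x0_").iloc[1].to_numpy())

    def test_theta0_outside_bounds_rejected(self, virtual_patient):
        pt = virtual_patient
        d = prepare_data(pt.pressure_obs, pt.flow_obs, Nt=50)
        with pytest.raises(ValueError):
            calibrate(d, pt.truth, theta0=pt.truth.theta() * 100)
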