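"""Bolus model evaluation, transition/baseline estimation, least-squares fit."""

import numpy as np
import pytest

from dsacolor.dsa_io import ValidationError
from dsacolor.tic_fitting import (
    T0A0Estimate,
    TicFit,
    bolus_model,
    estimate_t0_a0,
    fit_tic,
)

FPS = 6.0
T = 60
TIMES = np.arange(T) / FPS


class TestBolusModel:
    def test_zero_increment_is_flat(self):
        fit = TicFit(a0=12.0, a1=0.0, a2=0.3, a3=4.0, t0=2.0)
        assert np.allclose(bolus_model(TIMES, fit), 12.0)

    def test_decays_to_baseline(self):
        fit = TicFit(a0=5.0, a1=100.0, a2=0.5, a3=3.0, t0=1.0)
        assert bolus_model(1e4, fit) == pytest.approx(5.0, abs=1e-8)

    def test_step_limit_at_large_a3(self):
        fit = TicFit(a0=0.0, a1=100.0, a2=0.0, a3=1e3, t0=5.0)
        assert bolus_model(4.9, fit) < 1.0
        assert bolus_model(5.1, fit) > 99.0

    def test_no_overflow_for_extreme_a3(self):
        fit = TicFit(a0=0.0, a1=1.0, a2=0.1, a3=50.0, t0=9.0)
        with np.errstate(over="raise"):
            out = bolus_model(TIMES, fit)
        assert np.all(np.isfinite(out))


class TestEstimateT0A0:
    def test_hand_example(self):
        est = estimate_t0_a0([10, 10, 10, 40, 60, 60], FPS)
        assert est.detected
        assert est.t0 == pytest.approx(0.5)
        assert est.a0 == pytest.approx(10.0)

    def test_constant_series_not_detected(self):
        est = estimate_t0_a0([7.0] * 8, FPS)
        assert not est.detected
        assert est.a0 == 7.0
        assert np.isnan(est.t0)

    def test_transition_time_recovered_from_model(self):
        truth = TicFit(a0=0.0, a1=50.0, a2=0.05, a3=4.0, t0=2.0)
        est = estimate_t0_a0(bolus_model(TIMES, truth), FPS)
        assert est.detected
        assert abs(est.t0 - 2.0) <= 1 / FPS

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            estimate_t0_a0([1.0], FPS)


class TestFitTic:
    def test_noiseless_recovery_within_5pct(self):
        truth = TicFit(a0=0.0, a1=80.0, a2=0.1, a3=3.0, t0=1.5)
        series = bolus_model(TIMES, truth)
        fit = fit_tic(series, FPS, estimate_t0_a0(series, FPS))
        assert fit.converged
        assert fit.a1 == pytest.approx(80.0, rel=0.05)
        assert fit.a2 == pytest.approx(0.1, rel=0.05)
        assert fit.a3 == pytest.approx(3.0, rel=0.05)

    def test_flat_series_amplitude_at_lower_bound(self):
        series = np.full(T, 9.0)
        init = T0A0Estimate(t0=1.0, a0=9.0, detected=True)
        fit = fit_tic(series, FPS, init)
        assert fit.a1 == 0.0
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_short_series_rejected(self):
        init = T0A0Estimate(t0=0.5, a0=0.0, detected=True)
        with pytest.raises(ValidationError):
            fit_tic([0, 1, 2, 3, 4], FPS, init)

    def test_undetected_init_rejected(self):
        init = T0A0Estimate(t0=float("nan"), a0=0.0, detected=False)
        with pytest.raises(ValidationError):
            fit_tic(np.zeros(10), FPS, init)

    def test_fit_never_worse_than_initial_guess(self):
        rng = np.random.default_rng(42)
        truth = TicFit(a0=3.0, a1=60.0, a2=0.2, a3=8.0, t0=2.5)
        for _ in range(5):
            series = bolus_model(TIMES, truth) + rng.normal(0, 2.0, T)
            init = estimate_t0_a0(series, FPS)
            if not init.detected:
                continue
            fit = fit_tic(series, FPS, init)
            x0 = TicFit(a0=init.a0, a1=float(np.ptp(series)), a2=0.1, a3=2.0,
                        t0=init.t0)
            rss0 = float(((bolus_model(TIMES, x0) - series) ** 2).sum())
            assert fit.rss <= rss0 + 1e-9

    def test_reported_rss_is_self_consistent(self):
        truth = TicFit(a0=0.0, a1=40.0, a2=0.1, a3=6.0, t0=2.0)
        series = bolus_model(TIMES, truth) + np.sin(TIMES)  # deterministic residual
        fit = fit_tic(series, FPS, estimate_t0_a0(series, FPS))
        resid = bolus_model(TIMES, fit) - series
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-9)

    @pytest.mark.parametrize("shift", [-50.0, 13.7, 400.0])
    def test_shift_equivariance(self, shift):
        """Adding c to the series shifts a0 by c and keeps (a1, a2, a3)."""
        truth = TicFit(a0=0.0, a1=80.0, a2=0.1, a3=5.0, t0=2.0)
        series = bolus_model(TIMES, truth)
        base = fit_tic(series, FPS, estimate_t0_a0(series, FPS))
        moved = fit_tic(series + shift, FPS, estimate_t0_a0(series + shift, FPS))
        assert moved.a0 == pytest.approx(base.a0 + shift, abs=1e-9)
        assert moved.a1 == pytest.approx(base.a1, rel=1e-6)
        assert moved.a2 == pytest.approx(base.a2, rel=1e-6)
        assert moved.a3 == pytest.approx(base.a3, rel=1e-6)

    def test_bounds_respected(self):
        rng = np.random.default_rng(7)
        series = np.cumsum(rng.normal(1.0, 4.0, T))  # drifting series
        init = estimate_t0_a0(series, FPS)
        if init.detected:
            fit = fit_tic(series, FPS, init)
            assert 0 <= fit.a1 <= 10 * np.ptp(series)
            assert 0 <= fit.a2 <= 50 and 0 <= fit.a3 <= 50
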