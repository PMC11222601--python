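"""The five perfusion parameters and their per-pixel map assembly."""

import numpy as np
import pytest

from dsacolor.dsa_io import DsaSequence
from dsacolor.param_maps import (
    EmptyParamMapError,
    ParamConfig,
    build_param_map,
    build_param_maps,
    compute_auc,
    compute_flow,
    compute_toa,
    compute_transit,
    compute_ttp,
)
from dsacolor.phantom import upstream_quarter_mask
from dsacolor.preprocess import SegmentationConfig, VesselMask, segment_vessels
from dsacolor.tic_fitting import TicFit, bolus_model

FPS = 6.0
CFG = ParamConfig()


def test_default_threshold_is_15_percent():
    assert CFG.threshold_fraction == 0.15


class TestToa:
    def test_hand_example(self):
        toa, ok = compute_toa([0, 0, 0, 50, 100, 100], FPS, CFG)
        assert ok and toa == pytest.approx(0.5)

    def test_constant_series_invalid(self):
        _, ok = compute_toa([4.0] * 6, FPS, CFG)
        assert not ok


class TestTtp:
    def test_first_attainment_wins_ties(self):
        ttp, ok = compute_ttp([0, 10, 80, 80, 20], FPS, CFG)
        assert ok and ttp == pytest.approx(2 / 6)

    def test_constant_series_invalid(self):
        _, ok = compute_ttp([1.0] * 6, FPS, CFG)
        assert not ok


class TestTransit:
    def test_hand_example(self):
        series = [0, 0, 30, 100, 100, 100, 60, 10, 0, 0]
        transit, ok = compute_transit(series, FPS, CFG)
        assert ok and transit == pytest.approx(4 / 6)

    def test_monotone_series_has_no_fall(self):
        _, ok = compute_transit(np.arange(10.0), FPS, CFG)
        assert not ok

    @pytest.mark.parametrize("offset", [0.0, -20.0, 333.0])
    def test_invariant_to_constant_offset(self, offset):
        series = np.array([0, 0, 30, 100, 100, 100, 60, 10, 0, 0]) + offset
        transit, ok = compute_transit(series, FPS, CFG)
        assert ok and transit == pytest.approx(4 / 6)


class TestAuc:
    def test_zero_enhancement(self):
        fit = TicFit(a0=10.0, a1=0.0, a2=0.1, a3=3.0, t0=1.0)
        auc, ok = compute_auc(fit, CFG, FPS, n_frames=30)
        assert ok and auc == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_area(self):
        # flat enhancement of 10 units over a 2 s window
        fit = TicFit(a0=0.0, a1=10.0, a2=0.0, a3=1e4, t0=0.0)
        cfg = ParamConfig(window=(1.0, 3.0))
        auc, ok = compute_auc(fit, cfg, FPS)
        assert ok and auc == pytest.approx(20.0, rel=1e-9)

    def test_nonconverged_fit_invalid(self):
        fit = TicFit(a0=0, a1=5, a2=0.1, a3=3, t0=1, converged=False)
        _, ok = compute_auc(fit, CFG, FPS, n_frames=30)
        assert not ok

    def test_trapezoid_close_to_dense_quadrature(self):
        """Frame-rate trapezoid within 2% of 1000-subinterval quadrature."""
        fit = TicFit(a0=2.0, a1=90.0, a2=0.15, a3=20.0, t0=2.0)
        auc, _ = compute_auc(fit, CFG, FPS, n_frames=60)
        dense_t = np.linspace(0, 59 / FPS, 1001)
        dense = np.trapezoid(np.maximum(bolus_model(dense_t, fit) - 2.0, 0), dense_t)
        assert auc == pytest.approx(dense, rel=0.02)


class TestFlow:
    def test_zero_amplitude(self):
        fit = TicFit(a0=0.0, a1=0.0, a2=0.1, a3=3.0, t0=1.0)
        flow, ok = compute_flow(fit, CFG, FPS, n_frames=30)
        assert ok and flow == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_rise_slope(self):
        flows = []
        for a3 in (1.0, 5.0, 25.0):
            fit = TicFit(a0=0.0, a1=50.0, a2=0.05, a3=a3, t0=4.0)
            flow, ok = compute_flow(fit, CFG, FPS, n_frames=60)
            assert ok
            flows.append(flow)
        assert flows[0] < flows[1] < flows[2]

    def test_matches_symbolic_derivative_maximum(self):
        """Wash-in slope within 1% of the analytic dI/dt maximum (sympy)."""
        import sympy as sp

        fit = TicFit(a0=1.0, a1=120.0, a2=0.12, a3=18.0, t0=2.5)
        flow, _ = compute_flow(fit, CFG, FPS, n_frames=60)
        t = sp.symbols("t")
        expr = fit.a0 + fit.a1 * sp.exp(-fit.a2 * t) / (
            1 + sp.exp(-fit.a3 * (t - fit.t0))
        )
        d = sp.lambdify(t, sp.diff(expr, t), "numpy")
        oracle = d(np.linspace(0, 59 / FPS, 200001)).max()
        assert flow == pytest.approx(float(oracle), rel=0.01)


class TestMaps:
    def test_toa_monotone_along_tube(self, clean_phantom):
        mask = segment_vessels(clean_phantom.sequence, SegmentationConfig(sigma_px=0))
        toa = build_param_map(clean_phantom.sequence, mask, "toa")
        v = clean_phantom.vessel_mask & toa.valid
        # bin vessel pixels by true arrival; median estimated TOA must not decrease
        tt = clean_phantom.toa_true[v]
        est = toa.values[v]
        order = np.argsort(tt)
        bins = np.array_split(est[order], 8)
        medians = [np.median(b) for b in bins]
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_breakpoint_arrives_later_than_upstream(self, clean_phantom):
        mask = segment_vessels(clean_phantom.sequence, SegmentationConfig(sigma_px=0))
        toa = build_param_map(clean_phantom.sequence, mask, "toa")
        leak = clean_phantom.leak_mask & ~clean_phantom.vessel_mask & toa.valid
        up = upstream_quarter_mask(clean_phantom) & toa.valid
        assert np.median(toa.values[leak]) > np.median(toa.values[up])

    def test_toa_le_ttp_and_transit_nonnegative(self, clean_phantom):
        mask = segment_vessels(clean_phantom.sequence, SegmentationConfig(sigma_px=0))
        maps = build_param_maps(
            clean_phantom.sequence, mask, ["toa", "ttp", "transit"]
        )
        both = maps["toa"].valid & maps["ttp"].valid
        assert (maps["toa"].values[both] <= maps["ttp"].values[both] + 1e-12).all()
        tr = maps["transit"]
        assert (tr.values[tr.valid] >= 0).all()
        # transit valid implies toa valid
        assert not (tr.valid & ~maps["toa"].valid).any()

    def test_maps_invariant_to_uniform_offset(self, clean_phantom):
        mask = segment_vessels(clean_phantom.sequence, SegmentationConfig(sigma_px=0))
        shifted = DsaSequence(clean_phantom.sequence.frames + 77.0, fps=FPS)
        for kind in ("toa", "ttp", "transit"):
            a = build_param_map(clean_phantom.sequence, mask, kind)
            b = build_param_map(shifted, mask, kind)
            np.testing.assert_array_equal(a.valid, b.valid)
            np.testing.assert_allclose(
                a.values[a.valid], b.values[b.valid], atol=1e-9
            )

    def test_all_invalid_raises_empty_map_error(self):
        seq = DsaSequence(np.full((8, 16, 16), 5.0), fps=FPS)
        mask = VesselMask(np.ones((16, 16), dtype=bool), 1.0)
        with pytest.raises(EmptyParamMapError):
            build_param_map(seq, mask, "toa")


def test_window_validation():
    with pytest.raises(Exception):
        ParamConfig(threshold_fraction=0.0)
    with pytest.raises(Exception):
        ParamConfig(window=(3.0, 1.0))
    cfg = ParamConfig(window=(0.5, 2.0))
    assert cfg.frame_slice(60, FPS) == slice(3, 13)
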