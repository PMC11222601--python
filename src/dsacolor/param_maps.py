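"""Per-pixel perfusion parameters and their assembly into grayscale maps.

Five parameters summarize each pixel's time-intensity curve over a selected
time window:

- **TOA** (time of arrival, s): time of the first frame whose intensity
  exceeds baseline by more than 15% of the pixel's enhancement range
  (peak - baseline).  Red-early TOA maps are the display of choice for
  active bleeding.
- **TTP** (time to peak, s): time of the first frame attaining the window
  maximum.
- **TRANSIT** (s): interval between the 15% rise trigger and the first
  post-peak frame that falls below peak minus 15% of the range.
- **AUC** (intensity*s): trapezoidal integral of fitted enhancement
  (model minus baseline, clipped at 0) over the window.
- **FLOW** (intensity/s): maximum wash-in slope, i.e. the peak of the fitted
  curve's time derivative over the window.

TOA, TTP and TRANSIT are computed from the (smoothed) raw series; AUC and
FLOW from the fitted bolus curve.  The 15% trigger is taken relative to the
per-pixel enhancement range rather than the raw baseline: subtracted
angiography backgrounds sit near zero, where a ratio-to-baseline threshold
is numerically unstable, and a range-relative threshold is invariant to
adding a constant to the whole series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dsa_io import DsaSequence, ValidationError
from .preprocess import VesselMask
from .tic_fitting import T0A0Estimate, TicFit, bolus_model, estimate_t0_a0, fit_tic

__all__ = [
    "KINDS",
    "UNITS",
    "ParamConfig",
    "ParamMap",
    "EmptyParamMapError",
    "compute_toa",
    "compute_ttp",
    "compute_transit",
    "compute_auc",
    "compute_flow",
    "build_param_map",
    "build_param_maps",
]

KINDS = ("auc", "ttp", "toa", "transit", "flow")
UNITS = {
    "auc": "intensity*s",
    "ttp": "s",
    "toa": "s",
    "transit": "s",
    "flow": "intensity/s",
}


_NAN = float("nan")


class EmptyParamMapError(RuntimeError):
    """Raised when no pixel of a requested map is valid."""


@dataclass
class ParamConfig:
    """Settings shared by all parameter computations.

    threshold_fraction
        Rise/fall trigger as a fraction of the per-pixel enhancement range
        (default 0.15, i.e. the 15% criterion).
    window
        ``(t_start, t_end)`` seconds — the selected time region.  ``None``
        means the full sequence; a single global window, not per-pixel.
    """

    threshold_fraction: float = 0.15
    window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValidationError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.window is not None:
            t0, t1 = self.window
            if not (0 <= t0 < t1):
                raise ValidationError(f"invalid window {self.window}")

    def frame_slice(self, n_frames: int, fps: float) -> slice:
        """Frame-index slice covering the window (full range when None)."""
        if self.window is None:
            return slice(0, n_frames)
        t0, t1 = self.window
        if t1 > (n_frames - 1) / fps + 1e-9:
            raise ValidationError(
                f"window end {t1} s exceeds sequence duration {(n_frames - 1) / fps} s"
            )
        i0 = int(np.ceil(t0 * fps - 1e-9))
        i1 = int(np.floor(t1 * fps + 1e-9)) + 1
        return slice(i0, i1)


@dataclass
class ParamMap:
    """One per-pixel parameter image with its validity mask and units."""

    kind: str
    values: np.ndarray
    valid: np.ndarray
    units: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown parameter kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 2:
            raise ValidationError("values and valid must be matching 2D grids")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValidationError("non-finite values inside the valid mask")


# ---------------------------------------------------------------------------
# per-pixel scalar computations


def _windowed(series, fps: float, cfg: ParamConfig):
    series = np.asarray(series, dtype=np.float64)
    sl = cfg.frame_slice(series.size, fps)
    return series[sl], sl.start


def _rise_index(win, baseline: float, cfg: ParamConfig) -> Optional[int]:
    peak = float(win.max())
    if peak <= baseline:
        return None
    thr = baseline + cfg.threshold_fraction * (peak - baseline)
    above = np.nonzero(win > thr)[0]
    return int(above[0]) if above.size else None


def compute_toa(series, fps: float, cfg: ParamConfig) -> tuple[float, bool]:
    """Time of arrival: first frame exceeding baseline + 15% of the range.

    The baseline is the frame-difference ``a0`` estimate; the peak is the
    window maximum.  Returns ``(toa_seconds, valid)``; degenerate series
    (no rise) are invalid.
    """
    win, i0 = _windowed(series, fps, cfg)
    baseline = estimate_t0_a0(win, fps).a0
    idx = _rise_index(win, baseline, cfg)
    if idx is None:
        return _NAN, False
    return (i0 + idx) / fps, True


def compute_ttp(series, fps: float, cfg: ParamConfig) -> tuple[float, bool]:
    """Time to peak: first frame attaining the window maximum (earliest tie)."""
    win, i0 = _windowed(series, fps, cfg)
    if np.ptp(win) == 0:
        return _NAN, False
    return (i0 + int(win.argmax())) / fps, True


def compute_transit(series, fps: float, cfg: ParamConfig) -> tuple[float, bool]:
    """Transit time: from the 15% rise trigger to the post-peak 15% fall.

    The fall trigger is the first frame *after* the (first) peak whose
    intensity drops below ``peak - threshold_fraction * (peak - baseline)``.
    Invalid when either trigger is absent (e.g. washout not captured).
    """
    win, i0 = _windowed(series, fps, cfg)
    baseline = estimate_t0_a0(win, fps).a0
    rise = _rise_index(win, baseline, cfg)
    if rise is None:
        return _NAN, False
    peak_idx = int(win.argmax())
    peak = float(win[peak_idx])
    thr = peak - cfg.threshold_fraction * (peak - baseline)
    after = win[peak_idx + 1 :]
    below = np.nonzero(after < thr)[0]
    if below.size == 0:
        return _NAN, False
    fall = peak_idx + 1 + int(below[0])
    return (fall - rise) / fps, True


def compute_auc(
    fit: TicFit, cfg: ParamConfig, fps: float, n_frames: Optional[int] = None
) -> tuple[float, bool]:
    """Area under the fitted enhancement curve over the window.

    Trapezoidal integral of ``max(I(t) - a0, 0)`` sampled at the frame times.
    ``n_frames`` bounds the default (full-sequence) window; it is required
    when ``cfg.window`` is None.
    """
    if not fit.converged:
        return _NAN, False
    times = _window_times(cfg, fps, n_frames)
    enh = np.maximum(bolus_model(times, fit) - fit.a0, 0.0)
    return float(np.trapezoid(enh, times)), True


def compute_flow(
    fit: TicFit, cfg: ParamConfig, fps: float, n_frames: Optional[int] = None
) -> tuple[float, bool]:
    """Maximum wash-in slope of the fitted curve over the window.

    The analytic time derivative

        dI/dt = a1 exp(-a2 t) [a3 s(1-s) - a2 s],   s = expit(a3 (t - t0)),

    is evaluated on a grid at 10x the frame rate; the maximum is returned.
    Nonnegative whenever ``a1 > 0`` and the wash-in lies inside the window.
    """
    if not fit.converged:
        return _NAN, False
    times = _window_times(cfg, fps, n_frames)
    grid = np.linspace(times[0], times[-1], max(2, (times.size - 1) * 10 + 1))
    from scipy.special import expit

    s = expit(fit.a3 * (grid - fit.t0))
    deriv = fit.a1 * np.exp(-fit.a2 * grid) * (fit.a3 * s * (1.0 - s) - fit.a2 * s)
    return float(deriv.max()), True


def _window_times(cfg: ParamConfig, fps: float, n_frames: Optional[int]) -> np.ndarray:
    if cfg.window is None:
        if n_frames is None:
            raise ValidationError("n_frames required when cfg.window is None")
        sl = slice(0, n_frames)
    else:
        if n_frames is None:
            n_frames = int(np.floor(cfg.window[1] * fps + 1e-9)) + 1
        sl = cfg.frame_slice(n_frames, fps)
    return np.arange(sl.start, sl.stop) / fps


# ---------------------------------------------------------------------------
# map assembly


def _fit_pixel(series, fps: float) -> Optional[TicFit]:
    est = estimate_t0_a0(series, fps)
    if not est.detected or series.size < 6:
        return None
    fit = fit_tic(series, fps, est)
    return fit if fit.converged else None


def build_param_maps(
    seq: DsaSequence,
    mask: VesselMask,
    kinds,
    cfg: ParamConfig | None = None,
) -> dict[str, ParamMap]:
    """Compute several parameter maps in one pass, sharing per-pixel fits.

    Model-based kinds (AUC, FLOW) require a converged bolus fit per pixel;
    the fit is computed once even when both are requested.  Raw-series kinds
    (TOA, TTP, TRANSIT) are evaluated directly on the windowed series.
    Pixels outside the vessel mask are invalid in every map.
    """
    cfg = cfg or ParamConfig()
    kinds = [k.lower() for k in kinds]
    for k in kinds:
        if k not in KINDS:
            raise ValidationError(f"unknown parameter kind {k!r}")
    h, w = seq.shape
    if mask.mask.shape != (h, w):
        raise ValidationError("mask shape does not match sequence frames")
    need_fit = any(k in ("auc", "flow") for k in kinds)
    out = {
        k: ParamMap(
            kind=k,
            values=np.zeros((h, w)),
            valid=np.zeros((h, w), dtype=bool),
            units=UNITS[k],
        )
        for k in kinds
    }
    raw_ops = {"toa": compute_toa, "ttp": compute_ttp, "transit": compute_transit}
    ys, xs = np.nonzero(mask.mask)
    for y, x in zip(ys, xs):
        series = seq.frames[:, y, x]
        fit = _fit_pixel(series, seq.fps) if need_fit else None
        for k in kinds:
            if k in raw_ops:
                val, ok = raw_ops[k](series, seq.fps, cfg)
            elif fit is None:
                val, ok = _NAN, False
            elif k == "auc":
                val, ok = compute_auc(fit, cfg, seq.fps, seq.n_frames)
            else:  # flow
                val, ok = compute_flow(fit, cfg, seq.fps, seq.n_frames)
            if ok:
                out[k].values[y, x] = val
                out[k].valid[y, x] = True
    for k in kinds:
        if not out[k].valid.any():
            raise EmptyParamMapError(f"empty parameter map: no valid {k} pixel")
    return out


def build_param_map(
    seq: DsaSequence,
    mask: VesselMask,
    kind: str,
    cfg: ParamConfig | None = None,
) -> ParamMap:
    """Compute a single parameter map inside the vessel mask."""
    return build_param_maps(seq, mask, [kind], cfg)[kind.lower()]
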