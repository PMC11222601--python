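"""Bolus-model time-intensity curve (TIC) fitting.

Each vessel pixel's intensity over time is modelled by a bolus curve

    I(t) = a0 + a1 * exp(-a2 * t) / (1 + exp(-a3 * (t - t0)))

where ``a0`` is the baseline intensity before contrast arrives, ``a1`` the
contrast intensity increment, ``a2`` (1/s) the rate at which the peak
intensity is halved (wash-out), ``a3`` (1/s) the rising slope of the wash-in,
and ``t0`` (s) the transition point of the perfusion process.  The logistic
factor switches the enhancement on around ``t0`` at a steepness set by
``a3``; the exponential factor decays it at rate ``a2``.

Fitting is two-stage, per pixel and independent of execution order:

1. ``t0`` and ``a0`` are fixed from the frame-to-frame difference signal —
   ``t0`` is the time of the largest positive difference between consecutive
   frames, ``a0`` the mean intensity of all frames strictly before it.
2. ``(a1, a2, a3)`` are then estimated by bounded nonlinear least squares
   with ``(t0, a0)`` held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .dsa_io import ValidationError

__all__ = ["TicFit", "T0A0Estimate", "bolus_model", "estimate_t0_a0", "fit_tic"]

#: bounds on the rate constants (1/s); generous for 6 fps sequences
A2_MAX = 50.0
A3_MAX = 50.0
#: multiple of the per-pixel MAD of frame differences a jump must exceed
#: for the transition to count as detected
NOISE_FLOOR_K = 5.0


@dataclass
class TicFit:
    """Fitted bolus-model parameters for one pixel, plus fit diagnostics."""

    a0: float
    a1: float
    a2: float
    a3: float
    t0: float
    rss: float = 0.0
    converged: bool = True

    def __call__(self, t):
        return bolus_model(t, self)


@dataclass
class T0A0Estimate:
    """Frame-difference estimate of transition time and baseline.

    ``t0`` is NaN when no transition was detected (``detected=False``), in
    which case the pixel is excluded from model-based parameter maps.
    """

    t0: float
    a0: float
    detected: bool


def bolus_model(t, fit: TicFit):
    """Evaluate the bolus curve model at time(s) ``t`` (seconds).

    Vectorized over ``t``.  Implemented with the logistic sigmoid
    ``expit(a3*(t-t0)) = 1/(1+exp(-a3*(t-t0)))`` for numerical stability at
    large ``a3``.
    """
    t = np.asarray(t, dtype=np.float64)
    return fit.a0 + fit.a1 * np.exp(-fit.a2 * t) * expit(fit.a3 * (t - fit.t0))


def estimate_t0_a0(
    series,
    fps: float,
    noise_floor_k: float = NOISE_FLOOR_K,
    onset_fraction: float = 0.05,
) -> T0A0Estimate:
    """Estimate the perfusion transition time and baseline of one pixel.

    ``t0`` is the acquisition time of the frame with the maximum positive
    frame-to-frame intensity difference; ``a0`` is the mean of all frames
    strictly before that frame (the first frame's value when the maximum
    difference occurs at frame 1).  The transition counts as *detected* only
    when the maximum difference exceeds ``noise_floor_k`` times the median
    absolute deviation of all frame-to-frame differences of the pixel — a
    robust noise floor at the low frame counts of 6 fps DSA.

    The baseline is the mean of the frames *before the wash-in begins*: from
    the maximum-difference frame, the rise run is traced backwards while the
    frame-to-frame differences stay above ``onset_fraction`` of the maximum
    difference, and the frames preceding that run are averaged.  (A gradual
    wash-in starts rising several frames before its steepest frame; averaging
    up to the steepest frame would drag the baseline upward.)  When the jump
    lands on frame 1, the first frame's value is the baseline.

    A constant series yields ``detected=False`` with ``a0`` equal to the
    constant and ``t0 = NaN``.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise ValidationError("series must be 1D with at least 2 frames")
    diffs = np.diff(series)
    max_diff = float(diffs.max())
    if max_diff <= 0:
        return T0A0Estimate(t0=math.nan, a0=float(series[0]), detected=False)
    k = int(diffs.argmax()) + 1  # frame index where the largest jump lands
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    detected = max_diff > noise_floor_k * mad
    k_onset = k
    while k_onset > 1 and diffs[k_onset - 2] > onset_fraction * max_diff:
        k_onset -= 1
    a0 = float(series[:k_onset].mean())
    return T0A0Estimate(t0=k / fps, a0=a0, detected=bool(detected))


def fit_tic(
    series,
    fps: float,
    init: T0A0Estimate,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> TicFit:
    """Fit ``(a1, a2, a3)`` by bounded least squares with ``(t0, a0)`` fixed.

    Bounds: ``a1 in [0, 10*range(series)]``, ``a2 in [0, 50]``,
    ``a3 in [0, 50]``; initial guess ``a1 = range(series)``, ``a2 = 0.1``,
    ``a3 = 2``.  The optimizer never worsens the objective, so the returned
    residual sum of squares is at most that of the initial guess.  Optimizer
    failure is reported through ``converged=False``, not an exception.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.size < 6:
        raise ValidationError(
            f"need at least 6 observations to fit 3 parameters, got {series.size}"
        )
    if not init.detected:
        raise ValidationError("fit_tic requires a detected transition (init.detected)")
    t = np.arange(series.size) / fps
    rng = float(np.ptp(series))
    if rng == 0.0:
        # degenerate flat series: amplitude pinned at its lower bound
        resid = init.a0 - series
        return TicFit(
            a0=init.a0, a1=0.0, a2=0.0, a3=0.0, t0=init.t0,
            rss=float(resid @ resid), converged=True,
        )

    def residual(p):
        a1, a2, a3 = p
        return a1 * np.exp(-a2 * t) * expit(a3 * (t - init.t0)) + init.a0 - series

    res = least_squares(
        residual,
        x0=np.array([rng, 0.1, 2.0]),
        bounds=(np.zeros(3), np.array([10.0 * rng, A2_MAX, A3_MAX])),
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    a1, a2, a3 = (float(v) for v in res.x)
    return TicFit(
        a0=init.a0,
        a1=a1,
        a2=a2,
        a3=a3,
        t0=init.t0,
        rss=float(2.0 * res.cost),  # least_squares cost = 0.5 * sum(resid^2)
        converged=bool(res.status > 0),
    )
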