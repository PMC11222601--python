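"""Synthetic DSA phantom: a contrast bolus in a thin tubular vessel.

The generator emulates an ex-vivo bleeding rig — a thin tube ("vessel", in
the spirit of a dialyzer fiber) carrying a contrast bolus front, with an
optional breakpoint where contrast extravasates into a slowly filling,
slowly clearing blob — imaged at a low frame rate with additive Gaussian
noise.  Every phantom ships with its ground truth (vessel mask, leak mask,
per-pixel ideal arrival time), so the whole pipeline is testable without any
external data.

Per-pixel temporal profile after the ideal front arrives at time ``toa``:

    enhancement(t) = A * (1 - exp(-r * (t - toa))) * exp(-w * (t - toa))

with fill rate ``r`` and washout rate ``w`` (leak pixels use the leak fill
and clear rates; the leak clears *slower* than the vessel washes out — the
persistence signature of extravasated contrast in active bleeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .dsa_io import DsaSequence, ValidationError

__all__ = [
    "BreakpointSpec",
    "PhantomSpec",
    "PhantomTruth",
    "BatteryCase",
    "generate_phantom",
    "make_experiment_battery",
    "upstream_quarter_mask",
]

_PATH_STEP = 0.25  # px spacing of the densified centerline


@dataclass
class BreakpointSpec:
    """An extravasation site: where and how contrast leaks out of the tube.

    position_frac
        Arc-length fraction along the tube path at which the vessel is
        "cut" (0 = injection end, 1 = far end).
    leak_radius_px
        Radius of the roughly circular extravasation blob.
    leak_fill_rate, leak_clear_rate
        Fill and clearance rates (1/s) of the blob; clearance must be slower
        than the intravascular washout.
    spread_speed
        Radial propagation speed (px/s) of contrast through the blob, much
        slower than the intravascular front.
    """

    position_frac: float = 0.55
    leak_radius_px: float = 6.0
    leak_fill_rate: float = 0.8
    leak_clear_rate: float = 0.05
    spread_speed: float = 8.0


@dataclass
class PhantomSpec:
    """Geometry, kinematics and noise of one synthetic sequence.

    Defaults describe a 128x128, 10-second acquisition at 6 fps: a ~3 px
    radius tube, a bolus front at 40 px/s, enhancement amplitude 100 image
    units with a sharp wash-in (fill_rate 20/s, i.e. the front saturates a
    pixel within about one frame) and gentle washout, and i.i.d. Gaussian
    noise of 2 units.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 60
    fps: float = 6.0
    #: None -> a default 3-vertex polyline scaled to the image size
    tube_path: Optional[tuple] = None
    tube_radius_px: float = 3.0
    front_speed: float = 40.0
    bolus_amplitude: float = 100.0
    fill_rate: float = 20.0
    washout_rate: float = 0.15
    breakpoint: Optional[BreakpointSpec] = field(default_factory=BreakpointSpec)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_path is None:
            # bent tube crossing the field of view, scaled to the image
            h, w = self.height, self.width
            self.tube_path = (
                (100 / 128 * h, 14 / 128 * w),
                (44 / 128 * h, 52 / 128 * w),
                (64 / 128 * h, 114 / 128 * w),
            )
        if self.n_frames < 6:
            raise ValidationError(f"n_frames must be >= 6, got {self.n_frames}")
        if self.fps <= 0 or self.front_speed <= 0:
            raise ValidationError("fps and front_speed must be > 0")
        if self.tube_radius_px < 1:
            raise ValidationError("tube_radius_px must be >= 1")
        if self.breakpoint is not None:
            bp = self.breakpoint
            if bp.leak_radius_px < 1:
                raise ValidationError("leak_radius_px must be >= 1")
            if not bp.leak_clear_rate < self.washout_rate:
                raise ValidationError(
                    "leak_clear_rate must be < washout_rate "
                    "(extravasated contrast clears slower than intravascular)"
                )
            if not 0.0 <= bp.position_frac <= 1.0:
                raise ValidationError("breakpoint position_frac must be in [0, 1]")


@dataclass
class PhantomTruth:
    """A synthetic sequence bundled with its ground truth."""

    sequence: DsaSequence
    vessel_mask: np.ndarray
    leak_mask: np.ndarray
    toa_true: np.ndarray  # seconds; NaN off vessel_mask | leak_mask
    spec: PhantomSpec


@dataclass
class BatteryCase:
    """One labeled case of a phantom battery."""

    truth: PhantomTruth
    has_breakpoint: bool


def _densify(path, step: float = _PATH_STEP) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``step`` px; returns (points, arc lengths)."""
    pts = np.asarray(path, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("tube_path must be a polyline of >= 2 (row, col) points")
    segs = np.diff(pts, axis=0)
    seg_len = np.hypot(segs[:, 0], segs[:, 1])
    if np.any(seg_len == 0):
        raise ValidationError("tube_path has zero-length segments")
    dense, arcs = [], []
    total = 0.0
    for p, d, L in zip(pts[:-1], segs, seg_len):
        n = max(2, int(np.ceil(L / step)) + 1)
        frac = np.linspace(0.0, 1.0, n)[:-1]
        dense.append(p + frac[:, None] * d)
        arcs.append(total + frac * L)
        total += L
    dense.append(pts[-1:])
    arcs.append(np.array([total]))
    return np.concatenate(dense), np.concatenate(arcs)


def _profile(t: np.ndarray, toa: np.ndarray, amp: float, r: float, w: float):
    """Rise-then-washout enhancement; 0 before arrival."""
    tau = t[:, None] - toa[None, :]
    out = amp * (1.0 - np.exp(-r * np.clip(tau, 0.0, None))) * np.exp(
        -w * np.clip(tau, 0.0, None)
    )
    out[tau < 0] = 0.0
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one synthetic sequence with ground truth.

    A pixel on the tube at arc distance ``d`` from the injection end has
    ideal arrival time ``d / front_speed``; leak pixels begin filling when
    the front reaches the breakpoint and spread radially at the (slow) leak
    spread speed.  Identical spec (including seed) gives bit-identical
    output.
    """
    h, w = spec.height, spec.width
    dense, arcs = _densify(spec.tube_path)
    margin = spec.tube_radius_px
    if (
        dense[:, 0].min() < margin
        or dense[:, 1].min() < margin
        or dense[:, 0].max() > h - 1 - margin
        or dense[:, 1].max() > w - 1 - margin
    ):
        raise ValidationError("tube_path leaves the image bounds")

    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    tree = cKDTree(dense)
    dist, nearest = tree.query(coords, workers=-1)
    dist = dist.reshape(h, w)
    arc_of_nearest = arcs[nearest].reshape(h, w)

    vessel_mask = dist <= spec.tube_radius_px
    toa_true = np.full((h, w), np.nan)
    toa_true[vessel_mask] = arc_of_nearest[vessel_mask] / spec.front_speed

    leak_mask = np.zeros((h, w), dtype=bool)
    if spec.breakpoint is not None:
        bp = spec.breakpoint
        arc_break = bp.position_frac * arcs[-1]
        center = dense[np.argmin(np.abs(arcs - arc_break))]
        t_break = arc_break / spec.front_speed
        r_dist = np.hypot(yy - center[0], xx - center[1])
        leak_mask = r_dist <= bp.leak_radius_px
        leak_only = leak_mask & ~vessel_mask
        toa_true[leak_only] = t_break + r_dist[leak_only] / bp.spread_speed

    times = np.arange(spec.n_frames) / spec.fps
    frames = np.zeros((spec.n_frames, h, w))
    v_idx = np.nonzero(vessel_mask.ravel())[0]
    frames.reshape(spec.n_frames, -1)[:, v_idx] = _profile(
        times,
        toa_true.ravel()[v_idx],
        spec.bolus_amplitude,
        spec.fill_rate,
        spec.washout_rate,
    )
    if spec.breakpoint is not None:
        l_idx = np.nonzero((leak_mask & ~vessel_mask).ravel())[0]
        if l_idx.size:
            frames.reshape(spec.n_frames, -1)[:, l_idx] = _profile(
                times,
                toa_true.ravel()[l_idx],
                spec.bolus_amplitude,
                spec.breakpoint.leak_fill_rate,
                spec.breakpoint.leak_clear_rate,
            )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sigma, frames.shape)

    seq = DsaSequence(frames=frames, fps=spec.fps, source_path="")
    return PhantomTruth(
        sequence=seq,
        vessel_mask=vessel_mask,
        leak_mask=leak_mask,
        toa_true=toa_true,
        spec=spec,
    )


def upstream_quarter_mask(truth: PhantomTruth) -> np.ndarray:
    """Vessel pixels in the first quarter of the tube (by true arrival time)."""
    toa_v = truth.toa_true[truth.vessel_mask]
    cutoff = toa_v.max() / 4.0
    return truth.vessel_mask & (truth.toa_true <= cutoff)


def _random_path(rng: np.random.Generator, h: int, w: int, margin: float):
    """A 3-vertex polyline crossing the field of view, away from the borders."""
    y0 = rng.uniform(margin + 8, h - margin - 8)
    y1 = rng.uniform(margin + 8, h - margin - 8)
    ym = rng.uniform(margin + 8, h - margin - 8)
    return (
        (float(y0), float(margin + 4)),
        (float(ym), float(w / 2 + rng.uniform(-10, 10))),
        (float(y1), float(w - margin - 4)),
    )


def make_experiment_battery(
    n_cases: int,
    breakpoint_fraction: float = 0.8,
    seed: int = 0,
    noise_sigma: Optional[float] = None,
    size: tuple[int, int] = (96, 96),
    n_frames: int = 48,
) -> list[BatteryCase]:
    """Generate a labeled battery of randomized phantom cases.

    Specs are drawn from documented ranges (front speed 25-60 px/s, amplitude
    60-140, tube radius 2-4 px, noise 1-3 units unless ``noise_sigma``
    overrides); a fraction ``breakpoint_fraction`` of the cases contain a
    breakpoint, at a randomized arc position in [0.4, 0.7].  Deterministic
    given the seed.
    """
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    if not 0.0 <= breakpoint_fraction <= 1.0:
        raise ValidationError("breakpoint_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_break = int(round(breakpoint_fraction * n_cases))
    has_break = np.zeros(n_cases, dtype=bool)
    has_break[rng.permutation(n_cases)[:n_break]] = True
    h, w = size
    cases = []
    for i in range(n_cases):
        radius = float(rng.uniform(2.0, 4.0))
        bp = None
        if has_break[i]:
            bp = BreakpointSpec(
                position_frac=float(rng.uniform(0.4, 0.7)),
                leak_radius_px=float(rng.uniform(4.0, 8.0)),
                leak_fill_rate=float(rng.uniform(0.5, 1.2)),
                leak_clear_rate=float(rng.uniform(0.02, 0.08)),
            )
        spec = PhantomSpec(
            height=h,
            width=w,
            n_frames=n_frames,
            tube_path=_random_path(rng, h, w, radius + 2),
            tube_radius_px=radius,
            front_speed=float(rng.uniform(25.0, 60.0)),
            bolus_amplitude=float(rng.uniform(60.0, 140.0)),
            noise_sigma=(
                float(rng.uniform(1.0, 3.0)) if noise_sigma is None else noise_sigma
            ),
            breakpoint=bp,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(BatteryCase(truth=generate_phantom(spec), has_breakpoint=bool(has_break[i])))
    return cases
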