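"""Grayscale-to-color transformation of parameter maps.

A parameter map is first normalized onto [0, 1] by robust percentiles, then
passed through a color lookup table (LUT) defined by ordered stops, each a
position in [0, 1] with an RGB triple; colors between stops are linearly
interpolated in RGB.  The clinical arrival-time scale runs red (contrast
arrives first) through yellow to blue (arrives last), so early-arriving
extravasation lights up red against later venous blue.

Invalid pixels render as the background color (black by default, matching
the dark background of subtracted angiograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsa_io import ValidationError
from .param_maps import ParamMap

__all__ = ["ColorLut", "LUTS", "normalize_map", "apply_lut", "render_overlay"]


@dataclass
class ColorLut:
    """A piecewise-linear RGB lookup table.

    ``stops`` is an ordered list of ``(position, (r, g, b))`` with the first
    position at 0, the last at 1, positions strictly increasing and channel
    values in 0..255.
    """

    stops: list[tuple[float, tuple[int, int, int]]]
    n_entries: int = 256

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.stops]
        if len(pos) < 2 or pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValidationError("LUT stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("LUT stop positions must be strictly increasing")
        for _, rgb in self.stops:
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise ValidationError(f"invalid RGB triple {rgb}")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Interpolate colors for normalized values in [0, 1] -> uint8 RGB."""
        values = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
        pos = np.array([p for p, _ in self.stops])
        rgb = np.array([c for _, c in self.stops], dtype=np.float64)
        out = np.empty(values.shape + (3,), dtype=np.uint8)
        for ch in range(3):
            out[..., ch] = np.rint(np.interp(values, pos, rgb[:, ch])).astype(np.uint8)
        return out

    def table(self) -> np.ndarray:
        """Discretized ``(n_entries, 3)`` uint8 table (for export/preview)."""
        return self(np.linspace(0.0, 1.0, self.n_entries))


#: built-in LUTs; "toa-ryb" is the clinical arrival-time scale
LUTS: dict[str, ColorLut] = {
    "toa-ryb": ColorLut(
        stops=[(0.0, (255, 0, 0)), (0.5, (255, 255, 0)), (1.0, (0, 0, 255))]
    ),
}


def normalize_map(
    pmap: ParamMap, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> tuple[np.ndarray, np.ndarray]:
    """Affinely map valid values onto [0, 1] between two percentiles.

    The ``lo_pct`` percentile of the valid values maps to 0 and the
    ``hi_pct`` percentile to 1, with clipping; percentile rather than min-max
    normalization keeps single-pixel outliers from unstable fits from
    swallowing the dynamic range.  When all valid values are identical the
    whole map renders at 0.5 (documented convention).

    Returns ``(normalized grid, valid grid)``.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValidationError(f"bad percentiles ({lo_pct}, {hi_pct})")
    vals = pmap.values[pmap.valid]
    if vals.size == 0:
        raise ValidationError("parameter map has no valid pixel")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct])
    norm = np.zeros_like(pmap.values)
    if hi == lo:
        norm[pmap.valid] = 0.5
    else:
        norm[pmap.valid] = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    return norm, pmap.valid.copy()


def apply_lut(
    norm: np.ndarray,
    valid: np.ndarray,
    lut: ColorLut,
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Color a normalized grid through a LUT; invalid pixels get ``background``.

    Deterministic: the output depends only on (normalized values, valid mask,
    LUT, background), so re-rendering is bit-identical.
    """
    norm = np.asarray(norm, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if norm.shape != valid.shape:
        raise ValidationError("norm and valid shapes differ")
    img = np.empty(norm.shape + (3,), dtype=np.uint8)
    img[:] = np.asarray(background, dtype=np.uint8)
    img[valid] = lut(norm[valid])
    return img


def render_overlay(
    color: np.ndarray, reference_frame: np.ndarray, alpha: float
) -> np.ndarray:
    """Alpha-blend a color-coded map over a grayscale reference frame.

    The reference is min-max scaled to 0..255 and replicated across RGB;
    ``alpha=1`` returns the color image, ``alpha=0`` the grayscale reference
    rendered as RGB.
    """
    color = np.asarray(color)
    ref = np.asarray(reference_frame, dtype=np.float64)
    if color.shape[:2] != ref.shape:
        raise ValidationError(
            f"shape mismatch: color {color.shape[:2]} vs reference {ref.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    span = np.ptp(ref)
    gray = (ref - ref.min()) / span * 255.0 if span > 0 else np.zeros_like(ref)
    ref_rgb = np.repeat(gray[..., None], 3, axis=-1)
    blend = alpha * color.astype(np.float64) + (1.0 - alpha) * ref_rgb
    return np.rint(blend).astype(np.uint8)
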