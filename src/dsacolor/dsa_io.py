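"""Reading and writing DSA sequences, parameter maps and score tables.

A digital subtraction angiography (DSA) acquisition is a short grayscale
movie: one 2D x-ray frame every ``1/fps`` seconds while a contrast bolus
travels through the vasculature.  This module owns every on-disk format the
package touches — TIFF stacks (the primary interchange format), directories
of PNG/TIFF frames, multi-frame grayscale DICOM (read-only), 16-bit parameter
map TIFFs with JSON sidecars, 8-bit mask PNGs and CSV reader-score tables —
and all of the metadata conventions around them.

Intensity polarity is normalized at load time so that contrast arrival
*increases* stored intensity; every downstream definition (baseline, arrival
threshold, enhancement) relies on that convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

DEFAULT_FPS = 6.0  # typical low-dose DSA cine rate

__all__ = [
    "DsaSequence",
    "FormatError",
    "ValidationError",
    "load_sequence",
    "save_sequence",
    "load_scores",
    "save_mask",
    "load_mask",
    "save_param_map",
    "load_param_map",
]


class FormatError(RuntimeError):
    """Raised when an input file cannot be interpreted as a DSA sequence."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant (shape, range, ...)."""


@dataclass
class DsaSequence:
    """A time-ordered grayscale frame stack with its acquisition frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``, floating point.  Frame ``k`` is acquired
        at time ``k / fps`` seconds, counted from acquisition start (which the
        pipeline equates with contrast injection).
    fps
        Frames per second, strictly positive.
    polarity_inverted
        True if the raw input encoded contrast as *dark* and intensities were
        inverted on load so that contrast arrival increases intensity.
    source_path
        Provenance string (empty for in-memory sequences such as phantoms).
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    polarity_inverted: bool = False
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be (time, height, width); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError("a DSA sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frames contain non-finite values")
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        self.fps = float(self.fps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (height, width)."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame: ``{0, 1/fps, ..., (T-1)/fps}`` s."""
        return np.arange(self.n_frames) / self.fps

    @property
    def duration(self) -> float:
        """Time of the last frame, ``(T-1)/fps`` seconds."""
        return (self.n_frames - 1) / self.fps


def _normalize_polarity(frames: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip intensities if contrast arrival darkens the image.

    For each pixel take the signed temporal deviation from frame 0 with the
    largest magnitude; over the 1% of pixels with the strongest such change,
    a negative mean deviation means iodine is encoded dark, and the stack is
    inverted (``I <- max - I``).
    """
    dev = frames[1:] - frames[0]  # (T-1, H, W)
    idx = np.abs(dev).argmax(axis=0)
    signed = np.take_along_axis(dev, idx[None], axis=0)[0]
    mag = np.abs(signed).ravel()
    k = max(1, int(round(0.01 * mag.size)))
    top = np.argpartition(mag, mag.size - k)[mag.size - k :]
    if float(signed.ravel()[top].mean()) < 0:
        return frames.max() - frames, True
    return frames, False


def _fps_from_dicom(ds) -> Optional[float]:
    cine = getattr(ds, "CineRate", None)
    if cine:
        return float(cine)
    frame_time_ms = getattr(ds, "FrameTime", None)  # ms per frame
    if frame_time_ms:
        return 1000.0 / float(frame_time_ms)
    return None


def _read_dicom(path: Path) -> tuple[np.ndarray, Optional[float]]:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001 - wrapped into a domain error
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    interp = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if interp.startswith("MONOCHROME"):
        if arr.ndim == 2:
            raise ValidationError("single-frame DICOM: a sequence needs >= 2 frames")
        if arr.ndim != 3:
            raise FormatError(f"unsupported DICOM pixel layout {arr.shape}")
    else:
        raise FormatError(f"color DICOM ({interp}) is not supported; grayscale only")
    if interp == "MONOCHROME1":  # low values bright; flip to MONOCHROME2 convention
        arr = arr.max() - arr
    return np.asarray(arr, dtype=np.float64), _fps_from_dicom(ds)


def _read_frame_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise FormatError(f"directory {path} contains no PNG/TIFF frames")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:  # collapse RGB(A) frames to luminance
            img = img[..., :3].mean(axis=-1)
        frames.append(np.asarray(img, dtype=np.float64))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValidationError(f"frames of mismatched size in {path}: {sorted(shapes)}")
    return np.stack(frames)


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def load_sequence(path, fps_override: Optional[float] = None) -> DsaSequence:
    """Load a DSA sequence from a TIFF stack, frame directory, or DICOM file.

    Frame order for directories is strict lexicographic filename order.
    The frame rate is taken from DICOM CineRate/FrameTime when present, then
    from ``fps_override``, then the default of 6 fps.  Polarity is normalized
    so contrast arrival increases intensity.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fps = fps_override
    if path.is_dir():
        frames = _read_frame_dir(path)
    elif _is_dicom(path):
        frames, dicom_fps = _read_dicom(path)
        if dicom_fps is not None:
            fps = dicom_fps
    else:
        try:
            frames = tifffile.imread(str(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read {path} as a TIFF stack: {exc}") from exc
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 2:
            raise ValidationError("single-frame TIFF: a sequence needs >= 2 frames")
    frames, inverted = _normalize_polarity(frames)
    return DsaSequence(
        frames=frames,
        fps=float(fps) if fps else DEFAULT_FPS,
        polarity_inverted=inverted,
        source_path=str(path),
    )


def save_sequence(seq: DsaSequence, path) -> None:
    """Write a sequence as a lossless float64 TIFF stack.

    ``load_sequence(save_sequence(x))`` reproduces frame values exactly.
    """
    # re-validate: frames may have been mutated since construction
    seq = DsaSequence(
        frames=seq.frames, fps=seq.fps,
        polarity_inverted=seq.polarity_inverted, source_path=seq.source_path,
    )
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(str(path), seq.frames)


def load_scores(path):
    """Load a paired reader-score CSV into a :class:`~dsacolor.reader_eval.PairedScoreTable`.

    Requires columns ``case_id, score_dsa, score_combined`` (optionally
    ``truth``); scores are integers on the 1-5 diagnostic-confidence scale.
    """
    from .reader_eval import PairedScoreTable

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read score CSV {path}: {exc}") from exc
    return PairedScoreTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# masks and parameter maps


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_param_map(pmap, path) -> None:
    """Export a parameter map as 16-bit grayscale TIFF plus a JSON sidecar.

    Valid values are scaled affinely onto 0..65535; the sidecar (``<path>.json``)
    records the scale so the map can be reconstructed, plus kind and units.
    The validity mask is written as ``<stem>_valid.png``.
    """
    path = Path(path)
    vals = pmap.values[pmap.valid]
    if vals.size == 0:
        raise ValidationError("cannot export a parameter map with no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.zeros(pmap.values.shape, dtype=np.uint16)
    scaled[pmap.valid] = np.round((vals - lo) / span * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), scaled)
    save_mask(pmap.valid, path.with_name(path.stem + "_valid.png"))
    sidecar = {
        "kind": pmap.kind,
        "units": pmap.units,
        "scale_lo": lo,
        "scale_hi": hi,
        "n_valid": int(pmap.valid.sum()),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_param_map(path):
    """Reload a parameter map exported by :func:`save_param_map`."""
    from .param_maps import ParamMap

    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    scaled = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    valid = load_mask(path.with_name(path.stem + "_valid.png"))
    lo, hi = sidecar["scale_lo"], sidecar["scale_hi"]
    values = np.zeros_like(scaled)
    values[valid] = lo + scaled[valid] / 65535 * (hi - lo if hi > lo else 1.0)
    return ParamMap(
        kind=sidecar["kind"], values=values, valid=valid, units=sidecar["units"]
    )
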