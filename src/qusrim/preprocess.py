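"""RF-to-image conversion and reference-phantom depth correction.

This module turns raw radiofrequency (RF) echo frames into the two image
substrates consumed by the feature estimators:

* :class:`EnvelopeImage` -- magnitude of the per-line analytic signal,
  resampled onto an isotropic pixel grid (pixel size = line pitch), used by
  the envelope-statistics estimators;
* :class:`BModeImage` -- log-compressed envelope clipped to a fixed dB
  window, used by the texture estimators.

It also estimates depth-dependent correction curves from parametric maps of
a homogeneous reference phantom and applies them to lesion maps, removing
system/beam depth bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import h5py
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .features import ParametricMap

__all__ = [
    "RFFrame",
    "EnvelopeImage",
    "BModeImage",
    "CorrectionCurve",
    "detect_envelope",
    "log_compress",
    "estimate_correction_curve",
    "apply_correction",
    "read_rf_h5",
    "write_rf_h5",
]


@dataclass(frozen=True)
class RFFrame:
    """A single RF frame: real echo samples, axial (rows) by lateral (cols).

    Each column is one scan line sampled at ``fs_hz``; adjacent lines are
    ``line_pitch_mm`` apart laterally.
    """

    samples: np.ndarray
    fs_hz: float
    line_pitch_mm: float
    sound_speed_mps: float = 1540.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D (axial x lateral) array")
        if samples.shape[1] < 2:
            raise ValueError("RF frame needs at least 2 scan lines")
        if not np.all(np.isfinite(samples)):
            raise ValueError("RF samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.line_pitch_mm <= 0:
            raise ValueError("line pitch must be positive")
        if self.sound_speed_mps <= 0:
            raise ValueError("sound speed must be positive")

    @property
    def axial_spacing_mm(self) -> float:
        """Axial distance per RF sample (round-trip corrected), in mm."""
        return self.sound_speed_mps * 1e3 / (2.0 * self.fs_hz)

    @property
    def depth_mm(self) -> float:
        return (self.samples.shape[0] - 1) * self.axial_spacing_mm


@dataclass(frozen=True)
class EnvelopeImage:
    """Detected envelope on an isotropic pixel grid."""

    values: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("envelope must be 2-D")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed envelope, clipped to ``db_range`` (low, high) dB."""

    values_db: np.ndarray
    pixel_mm: float
    db_range: tuple[float, float] = (20.0, 100.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values_db, dtype=float)
        object.__setattr__(self, "values_db", values)
        object.__setattr__(self, "db_range", tuple(float(v) for v in self.db_range))
        low, high = self.db_range
        if low >= high:
            raise ValueError("db_range must satisfy low < high")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(values < low - 1e-9) or np.any(values > high + 1e-9):
            raise ValueError("values_db must lie inside db_range after clipping")


@dataclass(frozen=True)
class CorrectionCurve:
    """Per-depth correction of a parametric map.

    ``mode='multiplicative'`` stores factors (map value is multiplied);
    ``mode='additive'`` stores offsets (added to the map value).
    """

    parameter_name: str
    depth_mm: np.ndarray
    values: np.ndarray
    mode: str = "multiplicative"

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_mm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depth_mm", depth)
        object.__setattr__(self, "values", vals)
        if depth.ndim != 1 or vals.shape != depth.shape:
            raise ValueError("depth grid and correction values must be matching 1-D arrays")
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if self.mode == "multiplicative" and np.any(vals <= 0):
            raise ValueError("multiplicative correction factors must be positive")


def detect_envelope(rf: RFFrame) -> EnvelopeImage:
    """Detect the per-line analytic-signal envelope and resample it
    onto an isotropic grid with pixel size equal to the line pitch.

    Axial resampling is linear; envelope detection happens before
    resampling. An all-zero frame yields a zero envelope and a warning.
    """
    samples = rf.samples
    if not samples.any():
        warnings.warn("all-zero RF frame: returning zero envelope", stacklevel=2)
        env = np.zeros_like(samples)
    else:
        env = np.abs(hilbert(samples, axis=0))

    dz = rf.axial_spacing_mm
    pixel_mm = rf.line_pitch_mm
    depth = (samples.shape[0] - 1) * dz
    z_new = np.arange(0.0, depth + 1e-12, pixel_mm)
    pos = z_new / dz
    i0 = np.floor(pos).astype(int)
    i0 = np.clip(i0, 0, samples.shape[0] - 1)
    i1 = np.clip(i0 + 1, 0, samples.shape[0] - 1)
    frac = (pos - i0)[:, None]
    resampled = env[i0, :] * (1.0 - frac) + env[i1, :] * frac
    return EnvelopeImage(values=resampled, pixel_mm=pixel_mm)


def log_compress(env: EnvelopeImage, db_range: tuple[float, float] = (20.0, 100.0)) -> BModeImage:
    """Log-compress an envelope relative to its frame maximum.

    The frame maximum maps to the top of ``db_range``; everything below the
    window floor is clipped to it.
    """
    low, high = float(db_range[0]), float(db_range[1])
    if low >= high:
        raise ValueError("db_range must satisfy low < high")
    peak = float(env.values.max(initial=0.0))
    if peak <= 0:
        raise ValueError("cannot log-compress an all-zero envelope")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env.values / peak) + high
    db = np.clip(db, low, high)
    return BModeImage(values_db=db, pixel_mm=env.pixel_mm, db_range=(low, high))


def estimate_correction_curve(
    phantom_map: "ParametricMap",
    smooth_rows: int = 5,
    mode: str = "multiplicative",
) -> CorrectionCurve:
    """Estimate a depth correction curve from a homogeneous-phantom map.

    For the multiplicative mode the factor at depth ``z`` is the global map
    mean divided by the lateral mean of the row at ``z``; additive mode uses
    the difference instead. The raw curve is smoothed with a moving average
    over ``smooth_rows`` rows.
    """
    values = np.asarray(phantom_map.values, dtype=float)
    valid = np.asarray(phantom_map.valid, dtype=bool)
    if values.shape[0] < 2:
        raise ValueError("cannot smooth a correction curve from a single-row map")
    counts = valid.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("phantom map has rows without any valid window")
    row_means = np.where(valid, values, 0.0).sum(axis=1) / counts
    global_mean = float(np.where(valid, values, 0.0).sum() / valid.sum())
    size = min(int(smooth_rows), values.shape[0])
    if mode == "multiplicative":
        if np.any(row_means == 0):
            raise ValueError("zero row mean: multiplicative correction undefined")
        raw = global_mean / row_means
    elif mode == "additive":
        raw = global_mean - row_means
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    smooth = uniform_filter1d(raw, size=size, mode="nearest")
    return CorrectionCurve(
        parameter_name=phantom_map.parameter_name,
        depth_mm=np.asarray(phantom_map.depth_mm, dtype=float),
        values=smooth,
        mode=mode,
    )


def apply_correction(pmap: "ParametricMap", curve: CorrectionCurve) -> "ParametricMap":
    """Apply a depth correction curve to a parametric map (row-wise)."""
    if curve.parameter_name != pmap.parameter_name:
        raise ValueError(
            f"parameter mismatch: map {pmap.parameter_name!r} vs curve {curve.parameter_name!r}"
        )
    depth = np.asarray(pmap.depth_mm, dtype=float)
    if depth.shape != curve.depth_mm.shape or not np.allclose(depth, curve.depth_mm):
        raise ValueError("depth grids of map and correction curve do not match")
    if curve.mode == "multiplicative":
        corrected = pmap.values * curve.values[:, None]
    else:
        corrected = pmap.values + curve.values[:, None]
    return replace(pmap, values=corrected)


# ---------------------------------------------------------------------------
# HDF5 I/O


def write_rf_h5(path, frame: RFFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=frame.samples)
        f.create_dataset("fs_hz", data=float(frame.fs_hz))
        f.create_dataset("line_pitch_mm", data=float(frame.line_pitch_mm))
        f.create_dataset("sound_speed_mps", data=float(frame.sound_speed_mps))


def read_rf_h5(path) -> RFFrame:
    with h5py.File(path, "r") as f:
        return RFFrame(
            samples=f["rf"][()],
            fs_hz=float(f["fs_hz"][()]),
            line_pitch_mm=float(f["line_pitch_mm"][()]),
            sound_speed_mps=float(f["sound_speed_mps"][()]),
        )
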