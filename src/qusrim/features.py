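"""Per-window QUS parameter estimation and per-lesion feature reduction.

Twelve parameters are estimated in each sliding window:

* ``NAK`` -- Nakagami shape parameter of the envelope, by the method of
  moments: ``<A^2>^2 / var(A^2)`` with the population variance;
* ``ENT`` -- amplitude-weighted Shannon entropy of the envelope, with the
  per-sample probability estimated by an equal-width histogram of the
  window;
* ten texture parameters -- contrast, correlation, energy, homogeneity and
  variance of the gray-level co-occurrence matrix (GLCM) of the
  log-compressed image, computed separately for a vertical (``V``) and a
  horizontal (``H``) pixel displacement.

Maps of these values over the window raster are reduced to one scalar per
lesion, ROI and parameter by averaging the valid in-ROI window values
pooled over the lesion's two scan planes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    BModeImage,
    CorrectionCurve,
    EnvelopeImage,
    apply_correction,
    detect_envelope,
    log_compress,
)
from .roi import ROIMask, WindowGrid, assign_windows, external_rim, place_windows, rasterize_contour

logger = logging.getLogger(__name__)

#: Canonical parameter order; also the column order of the feature table.
PARAMETERS: tuple[str, ...] = (
    "NAK",
    "ENT",
    "CONV",
    "CONH",
    "CORV",
    "CORH",
    "ENEV",
    "ENEH",
    "HOMV",
    "HOMH",
    "VARV",
    "VARH",
)

ENVELOPE_PARAMETERS = ("NAK", "ENT")
TEXTURE_PARAMETERS = tuple(p for p in PARAMETERS if p not in ENVELOPE_PARAMETERS)

__all__ = [
    "PARAMETERS",
    "ENVELOPE_PARAMETERS",
    "TEXTURE_PARAMETERS",
    "GLCM",
    "ParametricMap",
    "nakagami_mom",
    "weighted_entropy",
    "quantize_db",
    "compute_glcm",
    "glcm_features",
    "build_parametric_map",
    "estimate_maps",
    "roi_average",
    "extract_features",
    "feature_columns",
]


@dataclass(frozen=True)
class GLCM:
    """A normalized gray-level co-occurrence matrix for one displacement."""

    matrix: np.ndarray
    direction: str  # 'vertical' | 'horizontal'
    displacement_px: int
    levels: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (self.levels, self.levels):
            raise ValueError("GLCM matrix shape does not match level count")
        if np.any(m < 0):
            raise ValueError("GLCM entries must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to unit sum")


@dataclass(frozen=True)
class ParametricMap:
    """Per-window parameter values on the window-centre raster."""

    parameter_name: str
    values: np.ndarray
    valid: np.ndarray
    depth_mm: np.ndarray  # depth of each map row (window-centre depth)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)
        if values.shape != valid.shape or values.ndim != 2:
            raise ValueError("values and valid mask must be matching 2-D arrays")
        if len(self.depth_mm) != values.shape[0]:
            raise ValueError("depth grid length must equal the number of map rows")


def nakagami_mom(amplitudes: np.ndarray) -> float:
    """Method-of-moments Nakagami shape parameter of an envelope block.

    Uses the population variance (divide by n). A constant block has zero
    variance and returns NaN (the window is then marked invalid in maps).
    """
    a = np.asarray(amplitudes, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    intensity = a * a
    mean = intensity.mean()
    var = intensity.var()
    if var == 0:
        return float("nan")
    return float(mean * mean / var)


def weighted_entropy(amplitudes: np.ndarray, n_bins: int = 40) -> float:
    """Amplitude-weighted entropy of an envelope block.

    Each sample contributes ``-w_i * P_i * log2(P_i)`` where ``w_i`` is the
    amplitude divided by the block's amplitude sum and ``P_i`` the
    histogram-estimated probability of the bin containing the sample. The
    histogram spans [min, max] of the block with ``n_bins`` equal-width
    bins. An all-zero block is invalid (NaN); a constant block has a single
    occupied bin and zero entropy.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    a = np.asarray(amplitudes, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    total = a.sum()
    if total <= 0:
        return float("nan")
    lo = a.min()
    hi = a.max()
    if hi == lo:
        return 0.0
    idx = np.minimum(((a - lo) * (n_bins / (hi - lo))).astype(int), n_bins - 1)
    prob = np.bincount(idx, minlength=n_bins) / a.size
    p_i = prob[idx]
    w = a / total
    return float(-(w * p_i * np.log2(p_i)).sum())


def quantize_db(values_db: np.ndarray, db_range=(20.0, 100.0), levels: int = 20) -> np.ndarray:
    """Quantize dB values into ``levels`` equal bins over ``db_range``.

    The top of the range falls into the highest bin (right-closed top bin).
    """
    low, high = db_range
    q = ((np.asarray(values_db, dtype=float) - low) * (levels / (high - low))).astype(int)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    block_db: np.ndarray,
    direction: str,
    displacement_px: int = 4,
    levels: int = 20,
    db_range=(20.0, 100.0),
) -> GLCM:
    """Co-occurrence matrix of a B-mode block for one displacement.

    Pairs are ordered (no transpose symmetrization) and counted for a single
    displacement vector: ``displacement_px`` rows down for ``'vertical'`` or
    columns right for ``'horizontal'``. The matrix is normalized to unit sum.
    """
    q = quantize_db(block_db, db_range=db_range, levels=levels)
    d = int(displacement_px)
    if d < 1:
        raise ValueError("displacement must be >= 1 pixel")
    if direction == "vertical":
        if q.shape[0] <= d:
            raise ValueError("block too small for vertical displacement")
        a, b = q[:-d, :], q[d:, :]
    elif direction == "horizontal":
        if q.shape[1] <= d:
            raise ValueError("block too small for horizontal displacement")
        a, b = q[:, :-d], q[:, d:]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    counts = np.bincount((a * levels + b).ravel(), minlength=levels * levels)
    matrix = counts.reshape(levels, levels) / counts.sum()
    return GLCM(matrix=matrix, direction=direction, displacement_px=d, levels=levels)


def glcm_features(g: GLCM) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity and variance of a GLCM.

    ``COR`` is NaN when either marginal standard deviation is zero (the
    window is then invalid for COR only).
    """
    m = g.matrix
    idx = np.arange(g.levels, dtype=float)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    p_i = m.sum(axis=1)
    p_j = m.sum(axis=0)
    mu_i = float(idx @ p_i)
    mu_j = float(idx @ p_j)
    var_i = float(((idx - mu_i) ** 2) @ p_i)
    var_j = float(((idx - mu_j) ** 2) @ p_j)
    con = float((diff2 * m).sum())
    ene = float((m * m).sum())
    hom = float((m / (1.0 + diff2)).sum())
    if var_i > 0 and var_j > 0:
        cor = float((idx - mu_i) @ m @ (idx - mu_j) / np.sqrt(var_i * var_j))
    else:
        cor = float("nan")
    return {"CON": con, "COR": cor, "ENE": ene, "HOM": hom, "VAR": var_i}


def _window_iter(windows: WindowGrid, select: np.ndarray | None):
    for i, a in enumerate(windows.corners_ax):
        for j, b in enumerate(windows.corners_lat):
            if select is None or select[i, j]:
                yield i, j, int(a), int(b)


def estimate_maps(
    envelope: EnvelopeImage,
    bmode: BModeImage | None,
    windows: WindowGrid,
    parameters: Sequence[str] = PARAMETERS,
    *,
    select: np.ndarray | None = None,
    entropy_bins: int = 40,
    displacement_mm: float = 0.3,
    gray_levels: int = 20,
) -> dict[str, ParametricMap]:
    """Estimate several parametric maps in a single pass over the windows.

    This is the bulk path used by feature extraction: each window's envelope
    and B-mode blocks are sliced and quantized once and shared by all
    requested estimators. Results are identical to building each map
    individually with :func:`build_parametric_map`.
    """
    unknown = [p for p in parameters if p not in PARAMETERS]
    if unknown:
        raise ValueError(f"unknown parameters: {unknown}")
    if select is not None and select.shape != windows.shape:
        raise ValueError("selection mask must match the window raster")
    want_env = [p for p in parameters if p in ENVELOPE_PARAMETERS]
    want_tex = [p for p in parameters if p in TEXTURE_PARAMETERS]
    if want_tex and bmode is None:
        raise ValueError("texture parameters require a B-mode image")
    wpx = windows.window_px
    disp = max(1, round(displacement_mm / windows.pixel_mm))
    out = {p: np.full(windows.shape, np.nan) for p in parameters}

    need_v = any(p.endswith("V") for p in want_tex)
    need_h = any(p.endswith("H") for p in want_tex)
    tex_possible = wpx > disp
    db_range = bmode.db_range if bmode is not None else (20.0, 100.0)

    for i, j, a, b in _window_iter(windows, select):
        if want_env:
            eb = envelope.values[a : a + wpx, b : b + wpx]
            if "NAK" in out:
                out["NAK"][i, j] = nakagami_mom(eb)
            if "ENT" in out:
                out["ENT"][i, j] = weighted_entropy(eb, n_bins=entropy_bins)
        if want_tex and tex_possible:
            db = bmode.values_db[a : a + wpx, b : b + wpx]
            for direction, needed, suffix in (
                ("vertical", need_v, "V"),
                ("horizontal", need_h, "H"),
            ):
                if not needed:
                    continue
                g = compute_glcm(
                    db, direction, displacement_px=disp, levels=gray_levels, db_range=db_range
                )
                feats = glcm_features(g)
                for name, value in feats.items():
                    key = name + suffix
                    if key in out:
                        out[key][i, j] = value

    depth = windows.center_depth_mm
    maps = {}
    for p in parameters:
        values = out[p]
        valid = np.isfinite(values)
        if not valid.any():
            raise ValueError(f"no valid windows for parameter {p}")
        maps[p] = ParametricMap(parameter_name=p, values=values, valid=valid, depth_mm=depth)
    return maps


def build_parametric_map(
    image: EnvelopeImage | BModeImage,
    windows: WindowGrid,
    parameter: str,
    *,
    select: np.ndarray | None = None,
    entropy_bins: int = 40,
    displacement_mm: float = 0.3,
    gray_levels: int = 20,
    correction: CorrectionCurve | None = None,
) -> ParametricMap:
    """Build a single parametric map over a window raster.

    ``NAK``/``ENT`` consume an :class:`EnvelopeImage`, texture parameters a
    :class:`BModeImage`. Invalid windows are masked; a map with no valid
    window raises. If a correction curve is given it is applied to the map.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if parameter in ENVELOPE_PARAMETERS:
        if not isinstance(image, EnvelopeImage):
            raise TypeError(f"{parameter} maps require an EnvelopeImage")
        maps = estimate_maps(
            image, None, windows, [parameter], select=select, entropy_bins=entropy_bins
        )
    else:
        if not isinstance(image, BModeImage):
            raise TypeError(f"{parameter} maps require a BModeImage")
        # the envelope argument is unused for pure texture maps
        dummy_env = EnvelopeImage(values=np.zeros(image.values_db.shape), pixel_mm=image.pixel_mm)
        maps = estimate_maps(
            dummy_env,
            image,
            windows,
            [parameter],
            select=select,
            displacement_mm=displacement_mm,
            gray_levels=gray_levels,
        )
    pmap = maps[parameter]
    if correction is not None:
        pmap = apply_correction(pmap, correction)
    return pmap


def roi_average(
    maps: Sequence[ParametricMap], selections: Sequence[np.ndarray]
) -> float:
    """Unweighted mean over valid in-ROI window values pooled across planes.

    Returns NaN when no valid in-ROI window exists (the caller flags the
    lesion and drops the feature).
    """
    if len(maps) != len(selections):
        raise ValueError("need one selection mask per map")
    pooled = []
    for pmap, sel in zip(maps, selections):
        sel = np.asarray(sel, dtype=bool)
        if sel.shape != pmap.values.shape:
            raise ValueError("selection mask does not match map shape")
        pooled.append(pmap.values[sel & pmap.valid])
    pooled = np.concatenate(pooled) if pooled else np.array([])
    if pooled.size == 0:
        return float("nan")
    return float(pooled.mean())


def feature_columns(group: str) -> list[str]:
    """Feature-table column names for an ROI group."""
    if group == "internal":
        return [f"{p}_int" for p in PARAMETERS]
    if group == "external":
        return [f"{p}_ext" for p in PARAMETERS]
    if group == "combined":
        return [f"{p}_int" for p in PARAMETERS] + [f"{p}_ext" for p in PARAMETERS]
    raise ValueError(f"unknown ROI group {group!r}")


def extract_features(
    lesions: Iterable,
    *,
    rim_width_mm: float = 5.0,
    window_mm: float = 1.0,
    overlap: float = 0.92,
    db_range: tuple[float, float] = (20.0, 100.0),
    gray_levels: int = 20,
    displacement_mm: float = 0.3,
    entropy_bins: int = 40,
    corrections: Mapping[str, CorrectionCurve] | None = None,
    window_rule: str = "center",
) -> pd.DataFrame:
    """Reduce a cohort to a per-lesion feature table.

    ``lesions`` is an iterable of objects with ``lesion_id``, ``label`` and
    ``planes`` (each plane providing ``frame`` and ``contour_mm``), e.g. a
    :class:`~qusrim.synth.Cohort`'s lesions. Each row carries the 12
    parameters averaged over the internal ROI and over the external rim
    (columns ``<PARAM>_int`` then ``<PARAM>_ext``). Lesions with any missing
    feature are dropped with a log entry.
    """
    rows = []
    for lesion in lesions:
        per_param: dict[str, dict[str, list[np.ndarray]]] = {
            p: {"int": [], "ext": []} for p in PARAMETERS
        }
        ok = True
        for plane in lesion.planes:
            frame = plane.frame if hasattr(plane, "frame") else plane[0]
            contour = plane.contour_mm if hasattr(plane, "contour_mm") else plane[1]
            env = detect_envelope(frame)
            bmode = log_compress(env, db_range=db_range)
            internal = rasterize_contour(
                contour, env.values.shape, env.pixel_mm, contour_id=lesion.lesion_id
            )
            if not internal.mask.any():
                ok = False
                break
            external = external_rim(internal, rim_width_mm=rim_width_mm)
            windows = place_windows(env.values.shape, env.pixel_mm, window_mm, overlap)
            sel_int = assign_windows(windows, internal, rule=window_rule)
            sel_ext = assign_windows(windows, external, rule=window_rule)
            maps = estimate_maps(
                env,
                bmode,
                windows,
                PARAMETERS,
                select=sel_int | sel_ext,
                entropy_bins=entropy_bins,
                displacement_mm=displacement_mm,
                gray_levels=gray_levels,
            )
            for p, pmap in maps.items():
                if corrections and p in corrections:
                    pmap = apply_correction(pmap, corrections[p])
                good = pmap.valid
                per_param[p]["int"].append(pmap.values[sel_int & good])
                per_param[p]["ext"].append(pmap.values[sel_ext & good])
        if not ok:
            logger.warning("dropping %s: empty internal ROI", lesion.lesion_id)
            continue
        row: dict[str, object] = {"lesion_id": lesion.lesion_id, "label": lesion.label}
        for p in PARAMETERS:
            for roi_key, suffix in (("int", "_int"), ("ext", "_ext")):
                vals = np.concatenate(per_param[p][roi_key])
                if vals.size == 0:
                    row[p + suffix] = float("nan")
                else:
                    row[p + suffix] = float(vals.mean())
        missing = [k for k, v in row.items() if isinstance(v, float) and np.isnan(v)]
        if missing:
            logger.warning("dropping %s: missing features %s", lesion.lesion_id, missing)
            continue
        rows.append(row)
    columns = ["lesion_id", "label"] + feature_columns("combined")
    return pd.DataFrame(rows, columns=columns)
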