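"""ROI construction: tumour masks, peritumoral rims, and sliding windows.

Coordinates are in mm, axial-down positive, with the pixel at row ``i``,
column ``j`` centred at ``(x, z) = (j * pixel_mm, i * pixel_mm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Polygon

__all__ = [
    "ROIMask",
    "WindowGrid",
    "rasterize_contour",
    "external_rim",
    "place_windows",
    "assign_windows",
]


@dataclass(frozen=True)
class ROIMask:
    """Boolean pixel mask on the B-mode grid, labelled internal or external."""

    mask: np.ndarray
    kind: str  # 'internal' | 'external'
    pixel_mm: float
    contour_id: str | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.kind not in ("internal", "external"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_mm**2


@dataclass(frozen=True)
class WindowGrid:
    """Raster of sliding-window placements, all fully inside the image.

    ``corners_ax``/``corners_lat`` are the top/left pixel indices of the
    window rows and columns; placements are their Cartesian product, so maps
    built on this grid have shape ``(len(corners_ax), len(corners_lat))``.
    """

    image_shape: tuple[int, int]
    pixel_mm: float
    window_px: int
    stride_px: int
    corners_ax: np.ndarray
    corners_lat: np.ndarray
    window_mm: float
    overlap: float

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.corners_ax), len(self.corners_lat))

    @property
    def n_windows(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def centers_ax(self) -> np.ndarray:
        return self.corners_ax + self.window_px // 2

    @property
    def centers_lat(self) -> np.ndarray:
        return self.corners_lat + self.window_px // 2

    @property
    def center_depth_mm(self) -> np.ndarray:
        return self.centers_ax * self.pixel_mm


def _clean_polygon(polygon_mm) -> np.ndarray:
    verts = np.asarray(polygon_mm, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("polygon must be an (n, 2) array of [x_mm, z_mm]")
    if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    poly = Polygon(verts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon is self-intersecting or degenerate")
    return verts


def rasterize_contour(
    polygon_mm,
    image_shape: tuple[int, int],
    pixel_mm: float,
    contour_id: str | None = None,
) -> ROIMask:
    """Rasterize a closed contour polygon into an internal ROI mask.

    A pixel belongs to the mask iff its centre lies inside the polygon.
    A polygon entirely outside the image yields an empty mask and a warning.
    """
    verts = _clean_polygon(polygon_mm)
    poly = Polygon(verts)
    h, w = image_shape
    xs = np.arange(w) * pixel_mm
    zs = np.arange(h) * pixel_mm
    xx, zz = np.meshgrid(xs, zs)
    inside = shapely.contains_xy(poly, xx.ravel(), zz.ravel()).reshape(h, w)
    if not inside.any():
        warnings.warn("contour lies outside the image: empty internal mask", stacklevel=2)
    return ROIMask(mask=inside, kind="internal", pixel_mm=pixel_mm, contour_id=contour_id)


def external_rim(
    internal: ROIMask,
    rim_width_mm: float = 5.0,
    exclusions: list[np.ndarray] | None = None,
) -> ROIMask:
    """Build the external ROI: the band of tissue within ``rim_width_mm``
    of the internal mask (Euclidean distance transform on the pixel grid),
    minus any exclusion masks (skin band, shadows, ...)."""
    if not internal.mask.any():
        raise ValueError("internal mask is empty: cannot build a rim")
    if rim_width_mm < 0:
        raise ValueError("rim width must be non-negative")
    dist = distance_transform_edt(~internal.mask, sampling=internal.pixel_mm)
    rim = (dist > 0) & (dist <= rim_width_mm)
    if exclusions:
        for excl in exclusions:
            excl = np.asarray(excl, dtype=bool)
            if excl.shape != rim.shape:
                raise ValueError("exclusion mask shape does not match image")
            rim &= ~excl
    if not rim.any():
        warnings.warn("external rim is empty", stacklevel=2)
    return ROIMask(
        mask=rim, kind="external", pixel_mm=internal.pixel_mm, contour_id=internal.contour_id
    )


def place_windows(
    image_shape: tuple[int, int],
    pixel_mm: float,
    window_mm: float = 1.0,
    overlap: float = 0.92,
) -> WindowGrid:
    """Place a regular raster of square sliding windows.

    The stride is ``round(window_px * (1 - overlap))``, clamped to at least
    one pixel; windows never extend past the image.
    """
    if pixel_mm <= 0 or window_mm <= 0:
        raise ValueError("pixel size and window size must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    window_px = max(1, round(window_mm / pixel_mm))
    h, w = image_shape
    if window_px > h or window_px > w:
        raise ValueError(f"{window_px}px window does not fit in image {image_shape}")
    stride = max(1, round(window_px * (1.0 - overlap)))
    return WindowGrid(
        image_shape=tuple(image_shape),
        pixel_mm=pixel_mm,
        window_px=window_px,
        stride_px=stride,
        corners_ax=np.arange(0, h - window_px + 1, stride),
        corners_lat=np.arange(0, w - window_px + 1, stride),
        window_mm=window_mm,
        overlap=overlap,
    )


def assign_windows(windows: WindowGrid, roi: ROIMask, rule: str = "center") -> np.ndarray:
    """Select the windows belonging to an ROI.

    Returns a boolean matrix over the placement raster. The default rule
    assigns a window to the ROI iff its centre pixel is inside the mask; the
    ``'majority'`` alternative requires >= 50% of the window's pixels inside.
    """
    if roi.mask.shape != windows.image_shape:
        raise ValueError("ROI mask and window grid are on different pixel grids")
    if abs(roi.pixel_mm - windows.pixel_mm) > 1e-12:
        raise ValueError("ROI mask and window grid have different pixel sizes")
    if rule == "center":
        return roi.mask[np.ix_(windows.centers_ax, windows.centers_lat)]
    if rule == "majority":
        wpx = windows.window_px
        out = np.zeros(windows.shape, dtype=bool)
        half = wpx * wpx / 2.0
        for i, a in enumerate(windows.corners_ax):
            for j, b in enumerate(windows.corners_lat):
                out[i, j] = roi.mask[a : a + wpx, b : b + wpx].sum() >= half
        return out
    raise ValueError(f"unknown assignment rule {rule!r}")
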