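"""Segmentation evaluation: Dice similarity coefficient and clinical lumen areas.

DSC(S_a, S_m) = 2|S_a ∩ S_m| / (|S_a| + |S_m|) × 100% compares an automatic
mask against a reference mask.  DSC is evaluated on Cartesian masks: on the
polar grid a pixel near the catheter covers far less physical area than one at
large radius, so polar-grid Dice would over-weight the catheter region.
Lumen area (pixel count × pixel area) per frame yields the area curve along a
pullback; its minimum is the MLA (minimal luminal area), the standard stenosis
severity measure.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.draw import polygon

from .contour import LumenContour
from .polar import contour_to_cartesian

log = logging.getLogger(__name__)


def contour_to_mask(contour: LumenContour | np.ndarray,
                    shape: tuple[int, int]) -> np.ndarray:
    """Polar lumen mask: true at (i, j) iff i < radius_by_column[j]."""
    radii = contour.radius_by_column if isinstance(contour, LumenContour) \
        else np.asarray(contour, dtype=float)
    nr, nc = shape
    if radii.size != nc:
        raise ValueError("contour width does not match mask shape")
    rows = np.arange(nr)[:, None]
    return rows < radii[None, :]


def contour_to_cartesian_mask(contour: LumenContour | np.ndarray,
                              out_shape: tuple[int, int],
                              center: tuple[float, float]) -> np.ndarray:
    """Rasterize the contour polygon as a filled Cartesian lumen mask."""
    radii = contour.radius_by_column if isinstance(contour, LumenContour) \
        else np.asarray(contour, dtype=float)
    pts = contour_to_cartesian(radii, center)
    rr, cc = polygon(pts[:, 0], pts[:, 1], shape=out_shape)
    mask = np.zeros(out_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient in percent; both-empty counts as 100."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.warning("both masks empty; DSC defined as 100")
        return 100.0
    inter = int((a & b).sum())
    return 200.0 * inter / (na + nb)


def lumen_area(mask: np.ndarray, pixel_area: float) -> float:
    """Lumen area in mm²: true-pixel count × per-pixel area (spacing²)."""
    if pixel_area is None or pixel_area <= 0:
        raise ValueError("pixel_area must be a positive mm² value")
    return float(np.asarray(mask, dtype=bool).sum()) * pixel_area


def area_curve(masks: list[np.ndarray], pixel_area: float) -> np.ndarray:
    """Per-frame lumen areas along a pullback."""
    if len(masks) == 0:
        raise ValueError("need at least one frame")
    return np.array([lumen_area(m, pixel_area) for m in masks])


def find_extrema(curve: np.ndarray) -> tuple[int, float, int, float]:
    """(MLA frame, MLA area, max frame, max area); ties go to the lowest index."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty area curve")
    imin = int(np.argmin(curve))
    imax = int(np.argmax(curve))
    return imin, float(curve[imin]), imax, float(curve[imax])
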