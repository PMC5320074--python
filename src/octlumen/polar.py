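"""Resampling between Cartesian catheter-centered frames and the polar (r, θ) grid.

IVOCT frames are acquired as A-lines (radial intensity profiles) around the
catheter axis; segmentation is done on the unwrapped polar image, where the
lumen boundary is a roughly horizontal curve.  This module provides the
forward unwrap, the inverse rewrap, and the mapping of per-angle boundary
radii back to Cartesian polygon vertices.

Conventions
-----------
* A polar frame has ``n_radii`` rows and ``n_angles`` columns.  Row 0 is the
  catheter axis (radius 0); one row corresponds to one Cartesian pixel of
  radius.  Column ``j`` corresponds to the angle ``θ_j = 2πj / n_angles``,
  measured clockwise from image "up" (decreasing row direction).  The column
  axis is periodic.
* Samples falling outside the source grid are set to 0.
* Interpolation is bilinear in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class CartesianFrame:
    """A catheter-centered Cartesian image.

    Parameters
    ----------
    pixels : ndarray
        2-D intensity grid (any real dtype; kept as given).
    center : tuple of float
        (row, col) of the catheter/imaging axis, in pixel units.
    pixel_spacing : float
        Physical size of one pixel in mm (isotropic).
    """

    pixels: np.ndarray
    center: tuple[float, float]
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        r, c = self.center
        nr, nc = self.pixels.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"center {self.center} lies outside the {nr}x{nc} grid")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class PolarFrame:
    """An unwrapped frame: rows are radial depth (A-scan direction), columns A-lines."""

    pixels: np.ndarray
    radial_step: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        nr, na = self.pixels.shape
        if nr < 8 or na < 8:
            raise ValueError("polar frames need at least 8 radii and 8 angles")

    @property
    def n_radii(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_angles(self) -> int:
        return self.pixels.shape[1]

    def theta(self, j: np.ndarray | float) -> np.ndarray | float:
        return 2.0 * np.pi * np.asarray(j) / self.n_angles


def _direction(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit offset (drow, dcol) for angle ``theta`` (clockwise from image up)."""
    return -np.cos(theta), np.sin(theta)


def max_radius(shape: tuple[int, int], center: tuple[float, float]) -> float:
    """Largest radius fully inside the grid from ``center``."""
    r, c = center
    return min(r, shape[0] - 1 - r, c, shape[1] - 1 - c)


def cartesian_to_polar(frame: CartesianFrame, n_radii: int = 512,
                       n_angles: int = 360) -> PolarFrame:
    """Unwrap a Cartesian frame onto the (r, θ) grid.

    The output value at (i, j) is the bilinear interpolation of the input at
    ``center + i * direction(θ_j)``; samples outside the grid are 0.
    """
    if n_radii < 8 or n_angles < 8:
        raise ValueError("need n_radii >= 8 and n_angles >= 8")
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    radii = np.arange(n_radii, dtype=float)
    drow, dcol = _direction(theta)
    rows = frame.center[0] + radii[:, None] * drow[None, :]
    cols = frame.center[1] + radii[:, None] * dcol[None, :]
    out = ndimage.map_coordinates(np.asarray(frame.pixels, dtype=float),
                                  [rows, cols], order=1, mode="constant", cval=0.0)
    return PolarFrame(out, radial_step=frame.pixel_spacing)


def polar_to_cartesian(frame: PolarFrame, out_shape: tuple[int, int],
                       center: tuple[float, float]) -> CartesianFrame:
    """Rewrap a polar frame into Cartesian space (inverse of :func:`cartesian_to_polar`).

    Pixels at radius ≥ ``n_radii`` rows from the center are 0.
    """
    nr, nc = out_shape
    if nr < 1 or nc < 1:
        raise ValueError("out_shape must be positive")
    rows, cols = np.mgrid[0:nr, 0:nc].astype(float)
    drow = rows - center[0]
    dcol = cols - center[1]
    r = np.hypot(drow, dcol)
    theta = np.mod(np.arctan2(dcol, -drow), 2.0 * np.pi)
    jcoord = theta * frame.n_angles / (2.0 * np.pi)
    # wrap-pad one column so bilinear interpolation crosses the angular seam
    padded = np.concatenate([frame.pixels, frame.pixels[:, :1]], axis=1)
    out = ndimage.map_coordinates(np.asarray(padded, dtype=float),
                                  [r, jcoord], order=1, mode="constant", cval=0.0)
    return CartesianFrame(out, center=center, pixel_spacing=frame.radial_step)


def contour_to_cartesian(radius_by_column: np.ndarray,
                         center: tuple[float, float],
                         radial_step: float = 1.0) -> np.ndarray:
    """Map per-column boundary radii to a closed polygon in Cartesian space.

    Returns an ``(n_angles, 2)`` array of (row, col) vertices in pixel units
    scaled by ``radial_step`` (pass 1.0 for pixels, the mm spacing for mm).
    The polygon is closed implicitly: vertex 0 follows the last vertex.
    """
    radii = np.asarray(radius_by_column, dtype=float)
    if radii.ndim != 1 or radii.size < 3:
        raise ValueError("contour must cover all angular columns (1-D, length >= 3)")
    if np.any(~np.isfinite(radii)):
        raise ValueError("contour has missing (non-finite) columns")
    n = radii.size
    theta = 2.0 * np.pi * np.arange(n) / n
    drow, dcol = _direction(theta)
    pts = np.stack([center[0] + radii * drow, center[1] + radii * dcol], axis=1)
    return pts * radial_step if radial_step != 1.0 else pts
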