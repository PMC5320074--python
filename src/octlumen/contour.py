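"""Boundary extraction from the level set and polynomial gap fitting.

After the evolution converges on the merged (guide-wire-free) frame, each
column's boundary radius is the first outward + → − sign change of ϕ, located
to sub-row accuracy by linear interpolation.  The radii are mapped back to the
original angular grid, and the gap left by the removed guide-wire columns is
filled by least-squares polynomial fitting through K flanking boundary points
on each side — the "conquer" half of the divide-and-conquer strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .guidewire import Interval

PROV_LEVELSET = 0
PROV_FITTED = 1


class SegmentationFailure(RuntimeError):
    """Raised when too few columns have a detectable boundary crossing."""


@dataclass
class LumenContour:
    """One boundary radius (row coordinate) per original angular column.

    provenance[j] is PROV_LEVELSET where the radius came from the converged
    level set and PROV_FITTED where it was polynomial-fitted across the
    guide-wire gap.
    """

    radius_by_column: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.radius_by_column = np.asarray(self.radius_by_column, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=int)
        if self.radius_by_column.shape != self.provenance.shape:
            raise ValueError("radius and provenance shapes differ")
        if np.any(~np.isfinite(self.radius_by_column)):
            raise ValueError("contour has undefined columns")

    @property
    def n_angles(self) -> int:
        return self.radius_by_column.size


@dataclass(frozen=True)
class FitParams:
    """Gap-fit parameters: K support points per side, polynomial order M.

    With the default 2K = 20 points an M = 9 fit is near-interpolatory and
    can oscillate on rough flanks (Runge); ``fallback_cubic`` substitutes a
    cubic whenever the fitted gap's total variation exceeds 3× the flanking
    boundary's.  Off by default.
    """

    K: int = 10
    M: int = 9
    fallback_cubic: bool = False

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 1:
            raise ValueError("K and M must be >= 1")
        if 2 * self.K <= self.M:
            raise ValueError("need 2K > M for a well-posed least-squares fit")


def extract_boundary(phi: np.ndarray, start_row: int = 0,
                     max_missing_frac: float = 0.2) -> np.ndarray:
    """Per-column boundary radius from the first outward + → − crossing of ϕ.

    Scanning each column from ``start_row`` outward, the first pair of rows
    where ϕ changes from positive to non-positive brackets the boundary; the
    crossing is located by linear interpolation.  Columns without a crossing
    are returned as NaN after neighbour interpolation fails only if ALL
    columns are missing; more than ``max_missing_frac`` missing raises
    :class:`SegmentationFailure`.
    """
    phi = np.asarray(phi, dtype=float)
    nr, nc = phi.shape
    radii = np.full(nc, np.nan)
    sub = phi[start_row:]
    pos = sub > 0
    crossing = pos[:-1] & ~pos[1:]
    for j in range(nc):
        idx = np.nonzero(crossing[:, j])[0]
        if idx.size == 0:
            continue
        k = idx[0]
        a, b = sub[k, j], sub[k + 1, j]
        frac = a / (a - b) if a != b else 0.5
        radii[j] = start_row + k + frac
    missing = np.isnan(radii)
    if missing.mean() > max_missing_frac:
        raise SegmentationFailure(
            f"{missing.sum()}/{nc} columns have no level-set crossing")
    if missing.any() and not missing.all():
        radii = fill_missing(radii)
    return radii


def fill_missing(radii: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN columns from neighbours (periodic axis)."""
    radii = np.asarray(radii, dtype=float).copy()
    n = radii.size
    good = ~np.isnan(radii)
    if not good.any():
        raise ValueError("no defined columns to interpolate from")
    if good.all():
        return radii
    cols = np.arange(n)
    # unwrap periodically: extend good samples one period each side
    gx = cols[good]
    gy = radii[good]
    xs = np.concatenate([gx - n, gx, gx + n])
    ys = np.concatenate([gy, gy, gy])
    radii[~good] = np.interp(cols[~good], xs, ys)
    return radii


def fit_gap(boundary: np.ndarray, interval: Interval,
            params: FitParams = FitParams(),
            n_radii: int | None = None) -> np.ndarray:
    """Fit the guide-wire gap with an M-order polynomial through 2K flanking points.

    ``boundary`` holds radii on the ORIGINAL grid (values inside the interval
    are ignored).  The abscissa is the unwrapped column index, so the gap and
    its flanks form one contiguous axis across the periodic seam.  Returns the
    fitted radii for the gap columns in interval order, clamped to
    (1, n_radii − 1) when ``n_radii`` is given.  If fewer than K valid points
    exist on a side, K is reduced to the available minimum as long as the fit
    stays overdetermined (2K ≥ M + 1), else raises ValueError.
    """
    boundary = np.asarray(boundary, dtype=float)
    n = boundary.size
    if interval.n_angles != n:
        raise ValueError("interval and boundary disagree on n_angles")
    width = interval.width()
    gap_unwrapped = interval.start + np.arange(width)  # may run past n

    k = params.K
    left = interval.start - 1 - np.arange(k)[::-1]      # ascending, left flank
    right = interval.start + width + np.arange(k)       # ascending, right flank
    lv = ~np.isnan(boundary[left % n])
    rv = ~np.isnan(boundary[right % n])
    if not (lv.all() and rv.all()):
        k_avail = min(int(lv.sum()), int(rv.sum()))
        if 2 * k_avail < params.M + 1:
            raise ValueError("too few valid flanking points for the fit order")
        left = left[lv][-k_avail:]
        right = right[rv][:k_avail]
    support = np.concatenate([left, right])
    x = support.astype(float)
    y = boundary[support % n]
    poly = Polynomial.fit(x, y, deg=params.M)
    fitted = poly(gap_unwrapped.astype(float))
    if params.fallback_cubic:
        tv_fit = np.abs(np.diff(fitted)).sum()
        tv_flank = np.abs(np.diff(y)).sum()
        if tv_fit > 3.0 * tv_flank:
            fitted = Polynomial.fit(x, y, deg=3)(gap_unwrapped.astype(float))
    if n_radii is not None:
        fitted = np.clip(fitted, 1.0, n_radii - 1.0)
    return fitted


def compose_contour(merged_boundary: np.ndarray, column_map: np.ndarray,
                    fitted: np.ndarray | None, interval: Interval | None,
                    n_angles: int) -> LumenContour:
    """Merge level-set radii (via column_map) and fitted gap radii into one contour.

    The level-set columns and the gap columns must be disjoint and jointly
    cover all original columns.
    """
    radii = np.full(n_angles, np.nan)
    prov = np.full(n_angles, -1, dtype=int)
    merged_boundary = np.asarray(merged_boundary, dtype=float)
    column_map = np.asarray(column_map, dtype=int)
    if merged_boundary.size != column_map.size:
        raise ValueError("merged boundary and column_map sizes differ")
    radii[column_map] = merged_boundary
    prov[column_map] = PROV_LEVELSET
    if interval is not None:
        gap_cols = interval.columns()
        if fitted is None or len(fitted) != gap_cols.size:
            raise ValueError("fitted radii do not match the gap width")
        if np.any(prov[gap_cols] == PROV_LEVELSET):
            raise ValueError("gap columns overlap level-set columns")
        radii[gap_cols] = fitted
        prov[gap_cols] = PROV_FITTED
    if np.any(prov < 0) or np.any(np.isnan(radii)):
        raise ValueError("contour has undefined columns (domains not exhaustive)")
    return LumenContour(radii, prov)
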