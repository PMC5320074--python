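"""Guide-wire shadow detection and removal — the "divide" half of divide-and-conquer.

The metal guide wire casts a dark radial shadow over a contiguous sector of
A-lines, occluding the lumen boundary there.  Because the wire drifts only
slowly along the pullback, the shadow forms a dark, river-like track in the
*stripe map*: the matrix whose row f holds the per-column intensity sums of
frame f, min-max normalized within the frame.  The track is segmented on the
stripe map (Otsu threshold + morphological cleanup) once for the whole
pullback; per frame, the occluded angular interval is the widest periodic run
of mask columns, and those columns are deleted so that the remaining boundary
is consecutive for the level-set stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import filters, morphology

from .polar import PolarFrame

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interval:
    """A periodic angular interval [start, end] of columns, inclusive; may wrap."""

    start: int
    end: int
    n_angles: int

    def width(self) -> int:
        return (self.end - self.start) % self.n_angles + 1

    def columns(self) -> np.ndarray:
        return (self.start + np.arange(self.width())) % self.n_angles

    def contains(self, col: int) -> bool:
        return (col - self.start) % self.n_angles < self.width()

    def jaccard(self, other: "Interval") -> float:
        a = set(self.columns().tolist())
        b = set(other.columns().tolist())
        return len(a & b) / len(a | b)


@dataclass
class MergedFrame:
    """A polar frame with the guide-wire columns deleted.

    ``column_map[k]`` is the original column index of merged column k; the kept
    columns start just after the removed interval, so the periodic seam of the
    original frame is re-glued inside the merged frame and the two cut edges
    are genuine image boundaries.
    """

    pixels: np.ndarray
    column_map: np.ndarray
    interval: Interval | None = None


def build_stripe_map(pullback: list[PolarFrame] | list[np.ndarray]) -> np.ndarray:
    """Stack per-frame normalized column sums into an (n_frames, n_angles) map.

    Each frame contributes one stripe: its per-column pixel sums, min-max
    normalized to [0, 1] within the frame.  A constant frame (degenerate
    normalization) maps to 0.5 everywhere.
    """
    if len(pullback) == 0:
        raise ValueError("empty pullback")
    arrays = [f.pixels if isinstance(f, PolarFrame) else np.asarray(f) for f in pullback]
    n_angles = arrays[0].shape[1]
    if any(a.shape[1] != n_angles for a in arrays):
        raise ValueError("all frames must share n_angles")
    rows = []
    for f, a in enumerate(arrays):
        s = a.sum(axis=0, dtype=float)
        lo, hi = s.min(), s.max()
        if hi - lo <= 0:
            log.warning("frame %d has constant column sums; stripe set to 0.5", f)
            rows.append(np.full(n_angles, 0.5))
        else:
            rows.append((s - lo) / (hi - lo))
    return np.stack(rows)


def segment_guidewire_map(stripe_map: np.ndarray, min_area: int = 30,
                          closing_radius: int = 2,
                          dilation_radius: int = 2) -> np.ndarray:
    """Binary shadow mask on the stripe map: Otsu + closing + area filter + dilation.

    The threshold is Otsu's on the map quantized to 256 bins; columns below it
    are shadow candidates.  Morphology treats the column axis periodically.
    """
    m = np.asarray(stripe_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("stripe map must be 2-D")
    if np.ptp(m) <= 0:
        log.warning("stripe map is constant; no guide wire detected")
        return np.zeros(m.shape, dtype=bool)
    thresh = filters.threshold_otsu(m, nbins=256)
    mask = m < thresh
    if not mask.any():
        log.warning("all-bright stripe map; empty guide-wire mask")
        return mask
    # operate on a 3x column tiling so closing/labelling see the periodic seam;
    # a component narrower than n_angles appears as full-size copies in each tile
    n = m.shape[1]
    tiled = np.concatenate([mask, mask, mask], axis=1)
    if closing_radius > 0:
        tiled = morphology.closing(tiled, morphology.disk(closing_radius))
    if min_area > 0:
        # drop components of area < min_area
        tiled = morphology.remove_small_objects(tiled, max_size=min_area - 1)
    if dilation_radius > 0:
        tiled = morphology.dilation(tiled, morphology.disk(dilation_radius))
    return tiled[:, n:2 * n].astype(bool)


def _periodic_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal periodic runs of True; starts in [0, n)."""
    n = row.size
    doubled = np.concatenate([row, row])
    runs: list[tuple[int, int]] = []
    run_start = None
    for i, v in enumerate(doubled):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if run_start < n:
                runs.append((run_start, i - run_start))
            run_start = None
    if run_start is not None and run_start < n:
        runs.append((run_start, 2 * n - run_start))
    # a run starting at column 0 while column n-1 is set is the tail of a
    # wrapping run already represented by its true start
    if row[0] and row[-1]:
        runs = [(s, ln) for s, ln in runs if s != 0]
    return [(s, min(ln, n - 1)) for s, ln in runs]


def track_from_mask(mask: np.ndarray, frame_index: int,
                    stripe_row: np.ndarray | None = None,
                    max_width: int | None = None) -> Interval | None:
    """Widest periodic run of shadow columns in one stripe-map row, or None.

    A single guide wire is assumed: if several disjoint runs survive, the
    widest is taken; ties are broken toward the run with the lowest mean
    stripe value when ``stripe_row`` is given, else toward the earliest run.
    A run wider than ``max_width`` is physically implausible for a wire
    shadow (it is the dark half of a wire-free frame's natural intensity
    variation) and is reported as a non-detection.
    """
    row = np.asarray(mask[frame_index], dtype=bool)
    n = row.size
    if not row.any():
        return None
    if row.all():
        log.warning("frame %d: mask covers all columns; treating as no "
                    "guide wire", frame_index)
        return None
    runs = _periodic_runs(row)
    best_len = max(ln for _, ln in runs)
    candidates = [(s, ln) for s, ln in runs if ln == best_len]
    if len(candidates) > 1 and stripe_row is not None:
        stripe_row = np.asarray(stripe_row, dtype=float)
        candidates.sort(key=lambda r: stripe_row[(r[0] + np.arange(r[1])) % n].mean())
    start, length = candidates[0]
    if max_width is not None and length > max_width:
        log.warning("frame %d: widest dark run spans %d of %d columns; "
                    "treating as no guide wire", frame_index, length, n)
        return None
    return Interval(start % n, (start + length - 1) % n, n)


def fill_missing_intervals(intervals: list[Interval | None]) -> list[Interval | None]:
    """Frames with no detected interval inherit the nearest detected frame's.

    Exploits the wire's spatial continuity along the pullback.  If no frame
    has a detection, all entries stay None (segmentation proceeds without
    removal).
    """
    detected = [i for i, iv in enumerate(intervals) if iv is not None]
    if not detected:
        return list(intervals)
    out: list[Interval | None] = []
    for i, iv in enumerate(intervals):
        if iv is not None:
            out.append(iv)
        else:
            nearest = min(detected, key=lambda d: abs(d - i))
            out.append(intervals[nearest])
    return out


def detect_guidewire(pullback, min_area: int = 30, closing_radius: int = 2,
                     dilation_radius: int = 2,
                     max_width_frac: float = 0.25) -> list[Interval | None]:
    """Pullback-wide detection: stripe map → mask → per-frame interval + fill-in.

    ``max_width_frac`` bounds a plausible shadow width as a fraction of the
    angular range; wider detections are discarded (wire-free pullback).
    """
    smap = build_stripe_map(pullback)
    mask = segment_guidewire_map(smap, min_area=min_area,
                                 closing_radius=closing_radius,
                                 dilation_radius=dilation_radius)
    max_width = int(round(max_width_frac * mask.shape[1]))
    intervals = [track_from_mask(mask, f, stripe_row=smap[f], max_width=max_width)
                 for f in range(mask.shape[0])]
    return fill_missing_intervals(intervals)


def remove_guidewire(frame: PolarFrame | np.ndarray,
                     interval: Interval | None) -> MergedFrame:
    """Delete the occluded columns and re-glue the rest in periodic order.

    The merged frame starts at the column just after the interval end, so the
    removed gap sits at the merged frame's left/right edges.
    """
    pixels = frame.pixels if isinstance(frame, PolarFrame) else np.asarray(frame)
    n = pixels.shape[1]
    if interval is None:
        return MergedFrame(pixels.copy(), np.arange(n), None)
    if interval.width() >= n:
        raise ValueError("interval covers all columns")
    first = (interval.end + 1) % n
    kept = (first + np.arange(n - interval.width())) % n
    return MergedFrame(pixels[:, kept].copy(), kept, interval)
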