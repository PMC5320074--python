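"""Readers and writers for pullbacks, contours, masks and metrics.

Input pullbacks are TIFF stacks or directories of PNG/JPEG frames in
lexicographic order; 8- and 16-bit integer images are normalized to [0, 1]
floats internally.  Contours are serialized as one CSV row per (frame,
angular column) with both polar (theta, radius) and Cartesian (x, y)
coordinates, plus the per-column provenance (level set vs polynomial fit).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .guidewire import Interval
from .polar import contour_to_cartesian

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return (img.astype(float) - info.min) / (info.max - info.min)
    return img.astype(float)


def read_pullback(path: str | Path) -> list[np.ndarray]:
    """Load an ordered pullback from a TIFF stack or an image directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        return [_normalize(iio.imread(p)) for p in files]
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return [_normalize(fr) for fr in stack]
    return [_normalize(iio.imread(path))]


def write_pullback_tiff(path: str | Path, frames: list[np.ndarray]) -> None:
    """Write float frames in [0,1] as a 16-bit TIFF stack."""
    arr = np.stack([np.asarray(f, dtype=float) for f in frames])
    tifffile.imwrite(path, np.clip(arr * 65535, 0, 65535).astype(np.uint16))


def write_contours_csv(path: str | Path, results,
                       center: tuple[float, float]) -> None:
    """One row per (frame, column): theta, radius and Cartesian position.

    ``results`` is a sequence of SegResult; failed frames are skipped.
    """
    rows = []
    for r in results:
        if not getattr(r, "ok", True) or r.contour is None:
            continue
        radii = r.contour.radius_by_column
        pts = contour_to_cartesian(radii, center)
        n = radii.size
        theta = 2.0 * np.pi * np.arange(n) / n
        for j in range(n):
            rows.append((r.frame_index, j, theta[j], radii[j],
                         pts[j, 1], pts[j, 0], int(r.contour.provenance[j])))
    pd.DataFrame(rows, columns=["frame", "column", "theta_rad", "radius_px",
                                "x_px", "y_px", "provenance"]).to_csv(
        path, index=False)


def read_contours_csv(path: str | Path) -> dict[int, np.ndarray]:
    """Per-frame boundary radii from a contours CSV (columns frame/column/radius_px)."""
    df = pd.read_csv(path)
    out: dict[int, np.ndarray] = {}
    for f, grp in df.groupby("frame"):
        grp = grp.sort_values("column")
        radii = np.full(int(grp["column"].max()) + 1, np.nan)
        radii[grp["column"].to_numpy()] = grp["radius_px"].to_numpy()
        out[int(f)] = radii
    return out


def write_truth_csv(path: str | Path, radii: np.ndarray) -> None:
    """Ground-truth boundary radii as a contours-compatible CSV."""
    n_frames, n_angles = radii.shape
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    rows = [(f, j, theta[j], radii[f, j])
            for f in range(n_frames) for j in range(n_angles)]
    pd.DataFrame(rows, columns=["frame", "column", "theta_rad",
                                "radius_px"]).to_csv(path, index=False)


def write_intervals_csv(path: str | Path,
                        intervals: list[Interval | None]) -> None:
    rows = [(f, iv.start if iv else -1, iv.end if iv else -1)
            for f, iv in enumerate(intervals)]
    pd.DataFrame(rows, columns=["frame", "start_col", "end_col"]).to_csv(
        path, index=False)


def write_mask_stack(path: str | Path, masks: list[np.ndarray]) -> None:
    tifffile.imwrite(path, np.stack(masks).astype(np.uint8) * 255)


def write_overlay_png(path: str | Path, image: np.ndarray,
                      radii: np.ndarray, center: tuple[float, float]) -> None:
    """Render the image with the contour polygon burnt in (red channel)."""
    from skimage.draw import polygon_perimeter

    img8 = np.clip(np.asarray(image, dtype=float) * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([img8, img8, img8], axis=-1)
    pts = contour_to_cartesian(radii, center)
    rr, cc = polygon_perimeter(pts[:, 0], pts[:, 1], shape=img8.shape)
    rgb[rr, cc] = (255, 40, 40)
    iio.imwrite(path, rgb)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
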