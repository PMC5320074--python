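"""Narrow N×1 Gaussian smoothing along the A-scan direction.

Blood artifacts and the catheter sheath are thin structures lying mostly
perpendicular to the A-scan (radial) direction, so a 1-D Gaussian applied
along each A-line suppresses them.  Because the kernel is one column wide,
lumen boundaries whose radius jumps abruptly between neighbouring A-lines
(guide-wire cut edges, bifurcation openings) are untouched — the failure mode
of an ordinary N×N Gaussian, which blurs those jumps and lets the level set
leak through.  A full N×N filter is provided for comparison experiments only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SmoothParams:
    """Narrow-filter parameters.

    N is the nominal kernel length in rows; an even N is widened to N+1 so the
    discrete kernel is symmetric and introduces no half-pixel boundary shift.
    sigma is the Gaussian standard deviation in rows.
    """

    N: int = 20
    sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def length(self) -> int:
        """Actual (odd) kernel length."""
        return self.N if self.N % 2 == 1 else self.N + 1


def narrow_gaussian_kernel(params: SmoothParams) -> np.ndarray:
    """Sampled Gaussian exp(-k²/2σ²), centered, normalized to sum 1."""
    n = params.length
    k = np.arange(n) - n // 2
    w = np.exp(-(k ** 2) / (2.0 * params.sigma ** 2))
    return w / w.sum()


def _pixels(frame):
    return frame if isinstance(frame, np.ndarray) else frame.pixels


def smooth_narrow(frame, params: SmoothParams = SmoothParams()) -> np.ndarray:
    """Convolve each column independently with the N×1 kernel (mirror borders).

    Accepts a raw array or any object with a ``.pixels`` attribute; returns
    the smoothed array (no cross-column mixing, ever).
    """
    img = np.asarray(_pixels(frame), dtype=float)
    if img.size == 0:
        raise ValueError("empty frame")
    kernel = narrow_gaussian_kernel(params)
    return ndimage.correlate1d(img, kernel, axis=0, mode="reflect")


def smooth_full(frame, N: int = 20, sigma: float = 4.0) -> np.ndarray:
    """Separable N×N Gaussian (mirror borders) — the comparison filter."""
    img = np.asarray(_pixels(frame), dtype=float)
    if img.size == 0:
        raise ValueError("empty frame")
    kernel = narrow_gaussian_kernel(SmoothParams(N=N, sigma=sigma))
    out = ndimage.correlate1d(img, kernel, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel, axis=1, mode="reflect")
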