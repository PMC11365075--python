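"""Non-learning baseline segmenters: Otsu thresholding and Canny edges.

Both are applied as *naive* mask predictors — Otsu's selected class is used
directly as the foreground, and Canny's edge pixels themselves form the
predicted mask — so that they can be scored interchangeably with the
learned methods. No morphological clean-up or region filling is applied.

Operator conventions (fixed so results are exactly reproducible):

* Otsu: intensities are quantized to 256 levels (``round(v*255)``); a
  candidate threshold ``t`` splits levels into dark (``<= t``) and bright
  (``> t``); the selected ``t`` maximizes the between-class variance
  ``w0*w1*(mu0-mu1)^2`` with ties broken toward the smallest ``t``.
  Default polarity takes the dark class as foreground (lung fields are
  dark). A constant image yields the constant as threshold and an
  all-background mask.
* Canny: Gaussian smoothing, 3x3 Sobel gradients (reflect boundary),
  non-maximum suppression along the gradient direction quantized to four
  sectors, then double-threshold hysteresis where thresholds are fractions
  of the maximum gradient magnitude and weak edges survive only if
  8-connected to a strong edge. Plateau ties in the suppression step keep
  the pixel whose forward neighbour is strictly smaller (strict ``>``
  forward, ``>=`` backward), so an ideal step edge yields a single
  one-pixel-wide line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pairs_io import as_gray_image

__all__ = ["CannyParams", "otsu_threshold", "canny_mask"]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass
class CannyParams:
    gaussian_sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def validate(self) -> None:
        if self.gaussian_sigma <= 0.0:
            raise ValueError("gaussian_sigma must be > 0")
        if not (0.0 <= self.low_threshold <= self.high_threshold <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= low <= high <= 1")


def otsu_threshold(image: np.ndarray, dark_foreground: bool = True
                   ) -> tuple[float, np.ndarray]:
    """Global Otsu threshold; returns (threshold intensity, predicted mask)."""
    img = as_gray_image(image)
    if img.size == 0:
        raise ValueError("image must be nonempty")
    levels = np.round(img * 255.0).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) <= 1:  # constant image: degenerate by convention
        return float(img.flat[0]), np.zeros_like(levels, dtype=np.uint8)

    level_vals = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                     # pixels with level <= t
    sum0 = np.cumsum(hist * level_vals)
    total = sum0[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (total - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    t = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    dark = levels <= t
    mask = dark if dark_foreground else ~dark
    return t / 255.0, mask.astype(np.uint8)


# per NMS sector: the forward neighbour offset (dy, dx); backward is its negation
_SECTOR_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with zero fill, so off-image neighbours never win a comparison."""
    out = np.zeros_like(a)
    src_y = slice(max(0, -dy), a.shape[0] - max(0, dy))
    src_x = slice(max(0, -dx), a.shape[1] - max(0, dx))
    dst_y = slice(max(0, dy), a.shape[0] - max(0, -dy))
    dst_x = slice(max(0, dx), a.shape[1] - max(0, -dx))
    out[dst_y, dst_x] = a[src_y, src_x]
    return out


def canny_mask(image: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Canny edge pixels as a binary mask."""
    params = params or CannyParams()
    params.validate()
    img = as_gray_image(image).astype(np.float64)

    smoothed = ndimage.gaussian_filter(img, params.gaussian_sigma)
    gx = ndimage.correlate(smoothed, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(smoothed, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    if mag.max() == 0.0:
        return np.zeros_like(img, dtype=np.uint8)

    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    sector = np.zeros_like(angle, dtype=np.int64)
    sector[(angle >= 22.5) & (angle < 67.5)] = 45
    sector[(angle >= 67.5) & (angle < 112.5)] = 90
    sector[(angle >= 112.5) & (angle < 157.5)] = 135

    keep = np.zeros_like(mag, dtype=bool)
    for sec, (dy, dx) in _SECTOR_OFFSETS.items():
        fwd = _shift(mag, -dy, -dx)   # value of the neighbour at (+dy, +dx)
        bwd = _shift(mag, dy, dx)     # value of the neighbour at (-dy, -dx)
        keep |= (sector == sec) & (mag > fwd) & (mag >= bwd)
    nms = np.where(keep, mag, 0.0)

    high = params.high_threshold * mag.max()
    low = params.low_threshold * mag.max()
    strong = keep & (nms >= high)
    candidate = keep & (nms >= low)
    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    good = np.unique(labels[strong])
    good = good[good != 0]
    edges = candidate & np.isin(labels, good)
    return edges.astype(np.uint8)
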