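"""Histogram of oriented gradients: signed gradient orientations in
[0°, 360°) binned into 8 equal 45° bins, weighted by gradient magnitude
and normalized to sum to 1.

Bin k covers [45k°, 45(k+1)°); a pure left-to-right ramp (gradient along
+x) lands entirely in bin 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .gradient import _NONZERO_TOL, _eroded, bbox_crop

__all__ = ["N_HOG_BINS", "hog_features"]

N_HOG_BINS = 8


def hog_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    if not mask.any():
        raise ValueError("empty ROI mask")
    img, mask = bbox_crop(img, mask)
    inner = _eroded(mask)
    if not inner.any():
        raise ValueError("eroded ROI mask is empty")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    mag = np.sqrt(gx**2 + gy**2)[inner]
    angle = np.degrees(np.arctan2(gy, gx))[inner] % 360.0
    usable = mag > _NONZERO_TOL
    if not usable.any():
        warnings.warn(
            "all gradients are zero: returning a uniform orientation histogram",
            stacklevel=2,
        )
        hist = np.full(N_HOG_BINS, 1.0 / N_HOG_BINS)
    else:
        bins = np.minimum(
            (angle[usable] // (360.0 / N_HOG_BINS)).astype(int), N_HOG_BINS - 1
        )
        hist = np.bincount(bins, weights=mag[usable], minlength=N_HOG_BINS)
        hist = hist / hist.sum()
    return {f"bin{k}": float(hist[k]) for k in range(N_HOG_BINS)}
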