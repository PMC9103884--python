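"""Gradient-matrix (GRA) features: moments of the Sobel gradient magnitude
over the ROI, computed on a 1-pixel-eroded mask so the 3×3 operator never
reads outside the ROI.

The raw 3×3 Sobel kernels are used unnormalized, so a unit in-plane ramp
(slope 1 intensity/pixel) yields a gradient magnitude of 8 — the constant
the sharpness metric and its tests rely on.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "GRADIENT_STAT_NAMES",
    "SOBEL_RAMP_RESPONSE",
    "gradient_magnitude",
    "gradient_features",
    "moment_stats",
]

GRADIENT_STAT_NAMES = ("mean", "variance", "skewness", "kurtosis", "nonzero_fraction")

#: |G| of an in-plane unit ramp under the raw 3×3 Sobel kernel.
SOBEL_RAMP_RESPONSE = 8.0

_NONZERO_TOL = 1e-12


def _eroded(mask: np.ndarray) -> np.ndarray:
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    return ndimage.binary_erosion(mask, structure=structure)


def bbox_crop(image: np.ndarray, mask: np.ndarray):
    """Crop image and mask to the mask's bounding box (identical feature
    values, since all families read in-mask pixels only)."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    return image[slices], mask[slices]


def gradient_magnitude(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient magnitude and the eroded mask it is valid on.

    Works on 2D slices and 3D volumes (one Sobel pass per axis).
    """
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if mask.shape != img.shape:
        raise ValueError("mask/image shape mismatch")
    if not mask.any():
        raise ValueError("empty ROI mask")
    img, mask = bbox_crop(img, mask)
    inner = _eroded(mask)
    if not inner.any():
        raise ValueError("eroded ROI mask is empty (ROI too thin for 3x3 operator)")
    grads = [ndimage.sobel(img, axis=ax, mode="nearest") for ax in range(img.ndim)]
    magnitude = np.sqrt(np.sum([g**2 for g in grads], axis=0))
    return magnitude, inner


def moment_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and Fisher (excess) kurtosis.

    Skewness and kurtosis of a constant sample are defined as 0.
    """
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    var = float(v.var())
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    c = v - mean
    skew = float((c**3).mean() / var**1.5)
    kurt = float((c**4).mean() / var**2 - 3.0)
    return mean, var, skew, kurt


def gradient_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean, variance, skewness and kurtosis of |G| plus the fraction of
    in-mask pixels with a nonzero gradient."""
    magnitude, inner = gradient_magnitude(image, mask)
    g = magnitude[inner]
    mean, var, skew, kurt = moment_stats(g)
    nonzero = float((g > _NONZERO_TOL).mean())
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "nonzero_fraction": nonzero,
    }
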