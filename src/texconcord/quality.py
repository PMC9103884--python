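"""Comparator image-quality metrics: ROI signal-to-noise ratio and
gradient-amplitude sharpness per matrix size and tissue.

Two SNR estimators are provided with explicit method tags, since "SNR"
means different things depending on whether a background air region is
available: ``within_roi`` (mean/std of the ROI itself, the default —
ROI-only exports have no background) and ``background`` (ROI mean over the
std of a disjoint noise region).

Sharpness is the mean Sobel gradient magnitude over the (eroded) ROI —
the same 3×3 operator as the gradient feature family.  When a pixel
spacing is supplied the gradient is expressed per mm, which makes the
value comparable across images acquired at different matrix sizes (larger
pixels mechanically inflate per-pixel differences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features.gradient import gradient_magnitude
from .phantom import PhantomSeries

__all__ = ["roi_snr", "roi_sharpness", "quality_report"]


def roi_snr(
    image: np.ndarray,
    roi_mask: np.ndarray,
    noise_mask: np.ndarray | None = None,
) -> float:
    """Signal-to-noise ratio of one ROI.

    Returns +inf (flagged, to be excluded from means) when the noise
    estimate is zero.  Invariant under global intensity scaling.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if roi_mask.shape != img.shape:
        raise ValueError("mask/image shape mismatch")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    signal = img[roi_mask].mean()
    if noise_mask is not None:
        noise_mask = np.asarray(noise_mask, dtype=bool)
        if not noise_mask.any():
            raise ValueError("empty noise mask")
        if (noise_mask & roi_mask).any():
            raise ValueError("noise mask must be disjoint from the ROI")
        noise = img[noise_mask].std()
    else:
        noise = img[roi_mask].std()
    if noise == 0.0:
        return float("inf")
    return float(signal / noise)


def roi_sharpness(
    image: np.ndarray, roi_mask: np.ndarray, pixel_spacing: float = 1.0
) -> float:
    """Mean Sobel gradient magnitude over the eroded ROI, per
    ``pixel_spacing`` unit (default: per pixel)."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    magnitude, inner = gradient_magnitude(image, roi_mask)
    return float(magnitude[inner].mean() / pixel_spacing)


def quality_report(series: PhantomSeries, estimator: str = "within_roi") -> pd.DataFrame:
    """Mean SNR and sharpness across subjects and slices, per
    (matrix size, tissue).  Sharpness is reported per mm using each
    acquisition's pixel spacing; infinite SNR values are excluded from the
    means."""
    if estimator != "within_roi":
        raise ValueError("only the within_roi estimator is series-wide")
    rows = []
    for m in series.matrix_sizes:
        spacing = series.spec(m).pixel_spacing_mm
        for tissue in series.tissues:
            snrs, sharps = [], []
            for rec in series.subjects:
                mask = rec.rois[tissue][m]
                for img in rec.images[m]:
                    s = roi_snr(img, mask)
                    if np.isfinite(s):
                        snrs.append(s)
                    sharps.append(roi_sharpness(img, mask, pixel_spacing=spacing))
            rows.append(
                {
                    "matrix_size": m,
                    "tissue": tissue,
                    "snr_mean": float(np.mean(snrs)) if snrs else float("nan"),
                    "sharpness_mean": float(np.mean(sharps)),
                    "estimator": estimator,
                }
            )
    return pd.DataFrame(rows)
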