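"""First-order (histogram) features: four moments of the in-mask
intensity distribution plus the 1/10/50/90/99 nearest-rank percentiles."""

from __future__ import annotations

import numpy as np

from .gradient import moment_stats

__all__ = ["HISTOGRAM_STAT_NAMES", "PERCENTILES", "histogram_features"]

PERCENTILES = (1, 10, 50, 90, 99)

HISTOGRAM_STAT_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
) + tuple(f"p{p:02d}" for p in PERCENTILES)


def histogram_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(np.ma.getdata(image), dtype=float)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    mean, var, skew, kurt = moment_stats(vals)
    out = {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}
    # nearest-rank percentile: smallest value with CDF >= p
    pcts = np.percentile(vals, PERCENTILES, method="inverted_cdf")
    for p, v in zip(PERCENTILES, pcts):
        out[f"p{p:02d}"] = float(v)
    return out
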