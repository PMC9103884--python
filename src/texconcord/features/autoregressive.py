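"""First-order causal autoregressive (AR) texture model.

Pixel brightness is modeled as a weighted sum of the four causal
neighbors under raster-scan order:

    I(x, y) ≈ θ1·I(x−1, y) + θ2·I(x−1, y−1) + θ3·I(x, y−1) + θ4·I(x+1, y−1)

(left, upper-left, upper, upper-right; x = column, y = row), fit by
ordinary least squares on mean-subtracted in-mask intensities.  The five
reported parameters are θ1–θ4 and the residual standard deviation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AR_STAT_NAMES", "AR_NEIGHBOR_OFFSETS", "ar_features", "simulate_ar_texture"]

AR_STAT_NAMES = ("theta1", "theta2", "theta3", "theta4", "sigma")

#: (drow, dcol) of the causal neighbors, in θ1..θ4 order.
AR_NEIGHBOR_OFFSETS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))

MIN_USABLE_PIXELS = 100


def _design(image: np.ndarray, mask: np.ndarray):
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    h, w = img.shape
    rows, cols = np.nonzero(mask)
    keep = (rows >= 1) & (cols >= 1) & (cols <= w - 2)
    rows, cols = rows[keep], cols[keep]
    valid = np.ones(rows.shape, dtype=bool)
    for dr, dc in AR_NEIGHBOR_OFFSETS:
        valid &= mask[rows + dr, cols + dc]
    rows, cols = rows[valid], cols[valid]
    if rows.size < MIN_USABLE_PIXELS:
        raise ValueError(
            f"AR model needs >= {MIN_USABLE_PIXELS} pixels with all four "
            f"causal neighbors in-mask, got {rows.size}"
        )
    mu = img[mask].mean()
    centered = img - mu
    y = centered[rows, cols]
    x = np.stack(
        [centered[rows + dr, cols + dc] for dr, dc in AR_NEIGHBOR_OFFSETS], axis=1
    )
    return x, y


def ar_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    x, y = _design(image, mask)
    gram = x.T @ x
    if np.linalg.matrix_rank(gram) < 4:
        raise ValueError("singular AR normal equations (constant ROI?)")
    theta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ theta
    return {
        "theta1": float(theta[0]),
        "theta2": float(theta[1]),
        "theta3": float(theta[2]),
        "theta4": float(theta[3]),
        "sigma": float(resid.std()),
    }


def simulate_ar_texture(
    theta: tuple[float, float, float, float],
    shape: tuple[int, int],
    noise_sigma: float = 1.0,
    seed: int = 0,
    burn_in: int = 16,
) -> np.ndarray:
    """Draw a texture from the causal AR model (for parameter-recovery
    checks).  ``burn_in`` extra rows/cols are generated and trimmed so the
    retained field is approximately stationary."""
    h, w = shape
    hh, ww = h + burn_in, w + 2 * burn_in
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sigma, size=(hh, ww))
    img = np.zeros((hh, ww))
    t1, t2, t3, t4 = theta
    for r in range(hh):
        for c in range(ww):
            v = eps[r, c]
            if c >= 1:
                v += t1 * img[r, c - 1]
            if r >= 1:
                if c >= 1:
                    v += t2 * img[r - 1, c - 1]
                v += t3 * img[r - 1, c]
                if c <= ww - 2:
                    v += t4 * img[r - 1, c + 1]
            img[r, c] = v
    return img[burn_in:, burn_in : burn_in + w]
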