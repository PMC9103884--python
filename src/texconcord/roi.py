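"""ROI handling: mask scaling across matrix sizes, intensity statistics,
±3σ normalization and gray-level quantization.

All statistics are *population* statistics over in-mask pixels (the ROI is
treated as the full population, which makes the ±3σ bounds and the tests
unambiguous).  Masks are boolean 2D (or 3D) arrays; non-rectangular masks
are supported everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROIStats",
    "QuantizedROI",
    "scale_roi",
    "roi_stats",
    "normalize_roi",
    "quantize_roi",
]


@dataclass(frozen=True)
class ROIStats:
    """Population intensity statistics of one ROI."""

    mean: float
    std: float
    min: float
    max: float
    pixel_count: int

    @property
    def min_norm(self) -> float:
        """Lower normalization bound μ − 3σ."""
        return self.mean - 3.0 * self.std

    @property
    def max_norm(self) -> float:
        """Upper normalization bound μ + 3σ."""
        return self.mean + 3.0 * self.std


@dataclass(frozen=True)
class QuantizedROI:
    """ROI reduced to ``n_levels`` gray levels.

    ``levels`` holds values in [0, n_levels-1] inside the mask and -1 outside.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bounds: tuple[float, float]

    def __post_init__(self):
        inm = self.levels[self.mask]
        if inm.size and (inm.min() < 0 or inm.max() >= self.n_levels):
            raise ValueError("quantized levels out of range")


def _check_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(image):
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {np.shape(image)}"
        )
    if not mask.any():
        raise ValueError("empty ROI mask")
    return mask


def scale_roi(mask: np.ndarray, from_matrix: int, to_matrix: int) -> np.ndarray:
    """Rescale a binary ROI mask from one acquisition matrix to another.

    Coordinates are scaled by ``to_matrix / from_matrix`` with
    nearest-neighbor rounding, so the mask area scales by the square of the
    ratio (up to ±1 boundary pixel rounding per side).  This mirrors ROI
    sizing proportional to the FOV and hence to the image area.
    """
    if from_matrix <= 0 or to_matrix <= 0:
        raise ValueError("matrix sizes must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot scale an empty mask")
    if from_matrix == to_matrix:
        return mask.copy()
    out_shape = tuple(
        int(round(s * to_matrix / from_matrix)) for s in mask.shape
    )
    # nearest-neighbor: sample the source at output pixel centers
    src_idx = [
        np.minimum(
            (np.floor((np.arange(n) + 0.5) * m / n)).astype(int), m - 1
        )
        for n, m in zip(out_shape, mask.shape)
    ]
    return mask[np.ix_(*src_idx)]


def roi_stats(image: np.ndarray, mask: np.ndarray) -> ROIStats:
    """Population statistics over in-mask pixels only."""
    mask = _check_mask(image, mask)
    vals = np.asarray(image, dtype=float)[mask]
    return ROIStats(
        mean=float(vals.mean()),
        std=float(vals.std()),  # population (ddof=0)
        min=float(vals.min()),
        max=float(vals.max()),
        pixel_count=int(vals.size),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def normalize_roi(image: np.ndarray, mask: np.ndarray) -> np.ma.MaskedArray:
    """±3σ-normalize an ROI to 8 bits.

    N(x,y) = round(255 · (I(x,y) − (μ−3σ)) / (6σ)), clipped to [0, 255];
    μ and σ are the population mean/std of the in-mask intensities.  Pixels
    at exactly μ−3σ map to 0, at μ+3σ to 255, at μ to 128 (round-half-up).
    Out-of-mask pixels are flagged invalid in the returned masked array.
    """
    mask = _check_mask(image, mask)
    stats = roi_stats(image, mask)
    if stats.std == 0.0:
        raise ValueError("degenerate ROI: zero intensity standard deviation")
    img = np.asarray(image, dtype=float)
    n = _round_half_up(255.0 * (img - stats.min_norm) / (6.0 * stats.std))
    n = np.clip(n, 0.0, 255.0).astype(np.uint8)
    return np.ma.MaskedArray(n, mask=~mask)


def quantize_roi(
    roi_image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 64,
    mode: str = "minmax",
    bit_depth: int = 8,
) -> QuantizedROI:
    """Reduce an ROI to ``n_levels`` gray levels for co-occurrence/run-length
    analysis.

    ``minmax``: level = floor(Ng · (I − min) / (max − min)), with the in-mask
    maximum clipped to level Ng−1 (the limit of the +ε formulation).
    ``full_range``: bounds are the bit-depth range [0, 2**bit_depth − 1];
    level = floor(Ng · I / 2**bit_depth), so the top intensity maps to Ng−1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = _check_mask(roi_image, mask)
    img = np.asarray(np.ma.getdata(roi_image), dtype=float)
    levels = np.full(img.shape, -1, dtype=np.int64)
    inm = img[mask]
    if mode == "minmax":
        lo, hi = float(inm.min()), float(inm.max())
        if hi == lo:
            warnings.warn(
                "constant ROI in minmax quantization: all levels set to 0",
                stacklevel=2,
            )
            levels[mask] = 0
            return QuantizedROI(levels, mask, n_levels, (lo, hi))
        q = np.floor(n_levels * (img - lo) / (hi - lo))
    elif mode == "full_range":
        lo, hi = 0.0, float(2**bit_depth - 1)
        q = np.floor(n_levels * img / float(2**bit_depth))
    else:
        raise ValueError(f"unknown quantization mode {mode!r}")
    levels[mask] = np.clip(q[mask], 0, n_levels - 1).astype(np.int64)
    return QuantizedROI(levels, mask, n_levels, (lo, hi))
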