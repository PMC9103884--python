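"""Gabor transform magnitudes.

For each of 4 orientations (0°, 45°, 90°, 135°) and 6 Gaussian envelope
sizes s ∈ {4, 6, 8, 12, 16, 24} the feature is the mean magnitude, over
in-mask pixels, of the complex Gabor response with σ_env = s/2 and
sinusoid wavelength λ = s (one cycle per envelope size, the common
one-octave tie).  Kernels are DC-free (zero mean), so a constant ROI
responds with ~0, and L1-normalized by their Gaussian envelope so the
magnitude reads as a local contrast amplitude.

Orientation θ is the carrier direction measured from the +x (column)
axis: θ = 0° responds to vertical stripes (intensity varying along x).
The ROI bounding box is filled with the in-mask mean outside the mask and
convolved via a shared FFT (one forward transform per ROI, one inverse
per kernel); kernel spectra are cached per (shape, size, orientation).
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

__all__ = ["GABOR_SIZES", "GABOR_ORIENTATIONS_DEG", "gabor_kernel", "gabor_features"]

GABOR_SIZES = (4, 6, 8, 12, 16, 24)
GABOR_ORIENTATIONS_DEG = (0, 45, 90, 135)

_HALF_WIDTH_SIGMAS = 2.5

_kernel_fft_cache: dict[tuple, np.ndarray] = {}


def gabor_kernel(size: float, orientation_deg: float) -> np.ndarray:
    """Complex, zero-mean, envelope-normalized Gabor kernel."""
    sigma = size / 2.0
    lam = float(size)
    half = int(np.ceil(_HALF_WIDTH_SIGMAS * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    theta = np.deg2rad(orientation_deg)
    # row axis points down; use -y so angles are counter-clockwise from +x
    xr = x * np.cos(theta) + (-y) * np.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    kernel = envelope * np.exp(2j * np.pi * xr / lam)
    # remove DC so constant inputs give zero response
    kernel = kernel - envelope * (kernel.sum() / envelope.sum())
    return kernel / envelope.sum()


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def gabor_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(np.ma.getdata(image), dtype=float)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    if not mask.any():
        raise ValueError("empty ROI mask")
    rs, cs = _bounding_box(mask)
    box = img[rs, cs].copy()
    boxmask = mask[rs, cs]
    if min(box.shape) < max(GABOR_SIZES):
        raise ValueError(
            f"ROI bounding box {box.shape} smaller than the largest Gabor "
            f"envelope ({max(GABOR_SIZES)} px)"
        )
    mean_val = box[boxmask].mean()
    box[~boxmask] = mean_val

    # surround the box with its mean so border responses are not biased by
    # implicit zeros (a constant ROI then responds with exactly 0)
    max_half = int(np.ceil(_HALF_WIDTH_SIGMAS * max(GABOR_SIZES) / 2.0))
    padded = np.pad(box, max_half, mode="constant", constant_values=mean_val)
    fshape = tuple(
        sp_fft.next_fast_len(n + 2 * max_half, real=False) for n in padded.shape
    )
    img_fft = sp_fft.fft2(padded, s=fshape)

    out: dict[str, float] = {}
    for ang in GABOR_ORIENTATIONS_DEG:
        for size in GABOR_SIZES:
            key = (fshape, size, ang)
            if key not in _kernel_fft_cache:
                kernel = gabor_kernel(size, ang)
                half = kernel.shape[0] // 2
                _kernel_fft_cache[key] = (sp_fft.fft2(kernel, s=fshape), half)
            kfft, half = _kernel_fft_cache[key]
            full = sp_fft.ifft2(img_fft * kfft)
            off0, off1 = max_half + half, max_half + half
            resp = full[
                off0 : off0 + box.shape[0], off1 : off1 + box.shape[1]
            ]
            out[f"mag_s{size}_{ang}"] = float(np.abs(resp)[boxmask].mean())
    return out
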