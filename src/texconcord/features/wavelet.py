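"""Haar wavelet sub-band energies (DWT family).

The masked bounding box of the ROI (out-of-mask pixels filled with the
in-mask mean to suppress boundary artifacts) is decomposed with the Haar
wavelet over four scales; at each scale the four sub-bands LL, LH, HL and
HH are produced by one `pywt.dwt2` step applied to the previous LL.  The
energy of a sub-band is the mean squared coefficient over positions whose
2×2-block support intersects the ROI mask.

Band naming: first letter = filter along rows (y), second = along columns
(x); LH (low-y/high-x) responds to vertical stripes, HL to horizontal
stripes.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["WAVELET_BANDS", "N_WAVELET_SCALES", "haar_features"]

WAVELET_BANDS = ("LL", "LH", "HL", "HH")
N_WAVELET_SCALES = 4
MIN_BBOX = 16


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def _downsample_any(mask: np.ndarray) -> np.ndarray:
    """2× block-downsample: a coarse cell is valid when any of its (up to)
    2×2 fine cells is valid.  Odd sizes are padded, matching pywt output
    shapes ceil(n/2)."""
    h, w = mask.shape
    ph, pw = h + (h % 2), w + (w % 2)
    padded = np.zeros((ph, pw), dtype=bool)
    padded[:h, :w] = mask
    return (
        padded[0::2, 0::2]
        | padded[1::2, 0::2]
        | padded[0::2, 1::2]
        | padded[1::2, 1::2]
    )


def haar_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(np.ma.getdata(image), dtype=float)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    if not mask.any():
        raise ValueError("empty ROI mask")
    rs, cs = _bounding_box(mask)
    box = img[rs, cs].copy()
    boxmask = mask[rs, cs]
    if min(box.shape) < MIN_BBOX:
        raise ValueError(
            f"ROI bounding box {box.shape} too small for {N_WAVELET_SCALES} "
            f"Haar scales; minimum is {MIN_BBOX}x{MIN_BBOX}"
        )
    box[~boxmask] = box[boxmask].mean()

    out: dict[str, float] = {}
    ll = box
    m = boxmask
    for scale in range(1, N_WAVELET_SCALES + 1):
        ll, (ch, cv, cd) = pywt.dwt2(ll, "haar")
        m = _downsample_any(m)
        # pywt: cH = horizontal-edge detail (high along rows) -> HL here
        bands = {"LL": ll, "LH": cv, "HL": ch, "HH": cd}
        support = m if m.any() else np.ones_like(m)
        for name in WAVELET_BANDS:
            coeffs = bands[name]
            out[f"{name}_s{scale}"] = float((coeffs[support] ** 2).mean())
    return out
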