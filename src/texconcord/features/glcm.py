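"""Gray-level co-occurrence matrices and the 11 classical Haralick
statistics, with full mask awareness: a pixel pair is counted only when
both pixels are inside the ROI mask.

2D directions are 0° (horizontal), 45°, 90° (vertical) and 135°; 3D uses
the 13 unique direction classes of the 26-neighborhood.  Distances 1–5
multiply the unit offset.  Matrices are symmetrized (each ordered pair
counted both ways) and normalized to probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..roi import QuantizedROI

__all__ = [
    "CooccurrenceMatrix",
    "DIRECTIONS_2D",
    "DIRECTIONS_3D",
    "GLCM_STAT_NAMES",
    "glcm",
    "glcm_features",
]

#: 2D unit offsets as (drow, dcol); angles follow the usual convention where
#: 0° pairs a pixel with its right neighbor and 45° with its upper-right.
DIRECTIONS_2D: dict[str, tuple[int, ...]] = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}

#: the 13 unique 3D direction classes (dz, dy, dx) of the 26-neighborhood.
DIRECTIONS_3D: dict[str, tuple[int, ...]] = {
    "z0y0x1": (0, 0, 1),
    "z0y1x0": (0, 1, 0),
    "z0y1x1": (0, 1, 1),
    "z0y1xm1": (0, 1, -1),
    "z1y0x0": (1, 0, 0),
    "z1y0x1": (1, 0, 1),
    "z1y0xm1": (1, 0, -1),
    "z1y1x0": (1, 1, 0),
    "z1ym1x0": (1, -1, 0),
    "z1y1x1": (1, 1, 1),
    "z1y1xm1": (1, 1, -1),
    "z1ym1x1": (1, -1, 1),
    "z1ym1xm1": (1, -1, -1),
}

GLCM_STAT_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "diff_variance",
    "diff_entropy",
)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric, probability-normalized co-occurrence matrix."""

    probabilities: np.ndarray
    direction: str
    distance: int
    n_pairs: int

    def __post_init__(self):
        s = float(self.probabilities.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix is not normalized")


def _resolve_offset(direction: str | tuple[int, ...], ndim: int) -> tuple[tuple[int, ...], str]:
    if isinstance(direction, str):
        table = DIRECTIONS_2D if ndim == 2 else DIRECTIONS_3D
        if direction not in table:
            raise ValueError(f"unknown direction {direction!r} for {ndim}D")
        return table[direction], direction
    off = tuple(int(d) for d in direction)
    if len(off) != ndim:
        raise ValueError(f"offset {off} does not match {ndim}D data")
    return off, ",".join(str(d) for d in off)


def _shifted_views(arr: np.ndarray, offset: tuple[int, ...]):
    """Views of ``arr`` at p and p + offset over the overlapping region."""
    src, dst = [], []
    for o, n in zip(offset, arr.shape):
        if abs(o) >= n:
            return None, None
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return arr[tuple(src)], arr[tuple(dst)]


def glcm(
    q: QuantizedROI,
    direction: str | tuple[int, ...],
    distance: int = 1,
) -> CooccurrenceMatrix:
    """Co-occurrence matrix of a quantized ROI at one direction/distance.

    Both pixels of a pair must lie inside the mask.  The matrix is
    symmetrized and normalized to probabilities.
    """
    if not 1 <= distance <= 5:
        raise ValueError("distance must be in 1..5")
    levels = q.levels
    unit, label = _resolve_offset(direction, levels.ndim)
    offset = tuple(distance * o for o in unit)
    ng = q.n_levels
    a, b = _shifted_views(levels, offset)
    ma, mb = _shifted_views(q.mask, offset)
    if a is None:
        raise ValueError(
            f"no valid pixel pairs for direction {label}, distance {distance}"
        )
    valid = ma & mb
    ia, ib = a[valid], b[valid]
    if ia.size == 0:
        raise ValueError(
            f"no valid pixel pairs for direction {label}, distance {distance}"
        )
    counts = np.bincount(ia * ng + ib, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T  # symmetrize: count each ordered pair both ways
    probs = counts / counts.sum()
    return CooccurrenceMatrix(probs, label, distance, int(ia.size))


def _entropy(p: np.ndarray) -> float:
    """−Σ p·ln p with 0·ln 0 = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 11 Haralick statistics of a normalized co-occurrence matrix.

    Entropies use the natural logarithm.  Sum variance is centered on the
    sum average; difference variance is the variance of the difference
    histogram.  Correlation of a degenerate (zero marginal variance)
    matrix is defined as 0.
    """
    p = m.probabilities
    s = float(p.sum())
    if abs(s - 1.0) > 1e-9:
        raise ValueError("matrix must be normalized to probabilities")
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)  # == py after symmetrization
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # sum histogram p_{x+y}(k), k = 0 .. 2(Ng-1)
    ksum = (ii + jj).astype(int).ravel()
    p_sum = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng - 1)
    kk = np.arange(2 * ng - 1, dtype=float)
    sum_average = float(kk @ p_sum)
    sum_variance = float(((kk - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)

    # difference histogram p_{|x−y|}(k), k = 0 .. Ng-1
    kdiff = np.abs(ii - jj).astype(int).ravel()
    p_diff = np.bincount(kdiff, weights=p.ravel(), minlength=ng)
    kd = np.arange(ng, dtype=float)
    diff_mean = float(kd @ p_diff)
    diff_variance = float(((kd - diff_mean) ** 2) @ p_diff)
    diff_entropy = _entropy(p_diff)

    entropy = _entropy(p.ravel())

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "diff_variance": diff_variance,
        "diff_entropy": diff_entropy,
    }
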