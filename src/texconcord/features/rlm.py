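"""Gray-level run-length matrices and the 5 classical run-length
statistics.  A run is a maximal set of collinear, equally-quantized,
consecutive in-mask pixels along a direction; runs end at the mask
boundary.

The matrix is built without per-line Python loops: for run length L the
boolean array A_L marks positions p where p, p+o, …, p+(L−1)o are all
in-mask with equal level; restricting A_L to run *starts* (p−o does not
continue the run) and differencing over L yields the count of maximal
runs of each exact length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..roi import QuantizedROI
from .glcm import _resolve_offset, _shifted_views

__all__ = [
    "RunLengthMatrix",
    "RLM_STAT_NAMES",
    "run_length_matrix",
    "rlm_features",
]

RLM_STAT_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
)


@dataclass(frozen=True)
class RunLengthMatrix:
    """counts[g, l] = number of maximal runs of level g with length l+1."""

    counts: np.ndarray
    direction: str
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _equal_neighbor(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """E[p] = p and p+o both in-mask with equal level (False where p+o
    falls outside the array)."""
    e = np.zeros(levels.shape, dtype=bool)
    a, b = _shifted_views(levels, offset)
    if a is None:
        return e
    ma, mb = _shifted_views(mask, offset)
    src = _shifted_views(e, offset)[0]
    src[...] = (a == b) & ma & mb
    return e


def run_length_matrix(
    q: QuantizedROI, direction: str | tuple[int, ...]
) -> RunLengthMatrix:
    levels, mask = q.levels, q.mask
    if not mask.any():
        raise ValueError("empty ROI")
    offset, label = _resolve_offset(direction, levels.ndim)
    e = _equal_neighbor(levels, mask, offset)
    back = tuple(-o for o in offset)
    # continues[p] = True when p−o extends the run into p
    continues = np.zeros(mask.shape, dtype=bool)
    eb, _ = _shifted_views(e, offset)
    if eb is not None:
        dstv = _shifted_views(continues, back)[0]
        dstv[...] = eb
    starts = mask & ~continues

    ng = q.n_levels
    per_level_ge: list[np.ndarray] = []  # S_L[g]: maximal runs of length >= L
    a = mask.copy()
    length = 0
    while True:
        s = starts & a
        if not s.any():
            break
        per_level_ge.append(np.bincount(levels[s], minlength=ng))
        # A_{L+1}[p] = A_L[p] & E[p + (L-1)*o], L being the current length
        shift_by = tuple(length * o for o in offset)
        length += 1
        ev = np.zeros(mask.shape, dtype=bool)
        ev_at_p, _ = _shifted_views(ev, shift_by)
        if ev_at_p is None:
            a = np.zeros_like(a)
            continue
        _, e_at_shift = _shifted_views(e, shift_by)
        ev_at_p[...] = e_at_shift  # ev[p] = e[p + (L-1)*o]
        a = a & ev

    max_len = len(per_level_ge)
    counts = np.zeros((ng, max_len), dtype=np.int64)
    for li in range(max_len):
        ge_l = per_level_ge[li]
        ge_next = per_level_ge[li + 1] if li + 1 < max_len else 0
        counts[:, li] = ge_l - ge_next
    return RunLengthMatrix(counts, label, int(mask.sum()))


def rlm_features(
    q: QuantizedROI, direction: str | tuple[int, ...]
) -> dict[str, float]:
    """Short/long-run emphasis, gray-level and run-length nonuniformity,
    and the fraction of the ROI covered per run (run percentage)."""
    rlm = run_length_matrix(q, direction)
    r = rlm.counts.astype(float)
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("no runs found (empty ROI)")
    lengths = np.arange(1, r.shape[1] + 1, dtype=float)
    runs_per_length = r.sum(axis=0)
    runs_per_level = r.sum(axis=1)
    return {
        "short_run_emphasis": float((runs_per_length / lengths**2).sum() / n_runs),
        "long_run_emphasis": float((runs_per_length * lengths**2).sum() / n_runs),
        "gray_level_nonuniformity": float((runs_per_level**2).sum() / n_runs),
        "run_length_nonuniformity": float((runs_per_length**2).sum() / n_runs),
        "run_percentage": float(n_runs / rlm.n_pixels),
    }
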