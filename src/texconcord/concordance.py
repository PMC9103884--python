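"""Lin's concordance correlation coefficient across acquisition matrix
sizes, and its aggregation into per-family and overall transition reports.

For a feature measured on the same subjects at two matrix sizes, Lin's
coefficient

    ρc = 2·cov(x, y) / (var(x) + var(y) + (mean(x) − mean(y))²)

combines Pearson correlation with penalties for mean and scale shifts:
ρc = 1 only for perfect agreement.  Population moments (divisor n) are the
default; a sample-moment switch exists for sensitivity checks.

Degenerate features (zero variance on both sides) have no defined ρc and
are excluded from averages; exclusion counts are reported.  A feature
constant on one side only evaluates cleanly to ρc = 0 and is kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CCCResult",
    "TransitionReport",
    "lins_ccc",
    "ccc_between_matrices",
    "aggregate_transitions",
    "neighboring_pairs",
    "all_pairs",
]

_ZERO_VAR_REL = 1e-20


@dataclass
class FeatureTable:
    """Per-subject feature matrix for one (matrix size, tissue, mode,
    normalization) stratum.  ``data``: DataFrame indexed by subject id with
    registry-ordered feature columns; ``families`` aligns with columns."""

    data: pd.DataFrame
    matrix_size: int
    tissue: str
    mode: str
    normalization: str
    families: list[str]

    def __post_init__(self):
        if len(self.families) != self.data.shape[1]:
            raise ValueError("families must align with feature columns")


@dataclass
class CCCResult:
    """Per-feature Lin's ρc between two matrix sizes, with the moment
    ingredients retained for audit."""

    table: pd.DataFrame  # feature, family, ccc, pearson, mu_i, mu_j, sigma_i, sigma_j
    matrix_pair: tuple[int, int]
    tissue: str
    mode: str
    normalization: str
    n_subjects: int

    @property
    def n_undefined(self) -> int:
        return int(self.table["ccc"].isna().sum())


def _moments(x: np.ndarray, y: np.ndarray, ddof: int):
    n = x.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    cx, cy = x - mx, y - my
    denom = n - ddof
    vx = (cx**2).sum(axis=0) / denom
    vy = (cy**2).sum(axis=0) / denom
    cov = (cx * cy).sum(axis=0) / denom
    return mx, my, vx, vy, cov


def lins_ccc(x, y, sample: bool = False) -> float:
    """Lin's concordance correlation coefficient of two paired vectors.

    Returns NaN (flagged undefined) when both vectors have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my, vx, vy, cov = _moments(x[:, None], y[:, None], ddof=1 if sample else 0)
    scale = max(1.0, float(mx[0] ** 2), float(my[0] ** 2))
    if vx[0] <= _ZERO_VAR_REL * scale and vy[0] <= _ZERO_VAR_REL * scale:
        return float("nan")
    return float(2.0 * cov[0] / (vx[0] + vy[0] + (mx[0] - my[0]) ** 2))


def ccc_between_matrices(
    a: FeatureTable, b: FeatureTable, sample: bool = False
) -> CCCResult:
    """Per-feature ρc over the paired subject vectors of two strata."""
    for attr in ("tissue", "mode", "normalization"):
        if getattr(a, attr) != getattr(b, attr):
            raise ValueError(
                f"tables differ in {attr}: {getattr(a, attr)!r} vs {getattr(b, attr)!r}"
            )
    if a.matrix_size == b.matrix_size:
        raise ValueError("tables must come from different matrix sizes")
    if list(a.data.columns) != list(b.data.columns):
        raise ValueError("feature columns differ between tables")
    sa, sb = set(a.data.index), set(b.data.index)
    if sa != sb:
        raise ValueError(
            f"subject sets differ: only-in-a={sorted(sa - sb)}, "
            f"only-in-b={sorted(sb - sa)}"
        )
    xa = a.data.to_numpy(dtype=float)
    xb = b.data.loc[a.data.index].to_numpy(dtype=float)
    mx, my, vx, vy, cov = _moments(xa, xb, ddof=1 if sample else 0)

    scale = np.maximum(1.0, np.maximum(mx**2, my**2))
    undefined = (vx <= _ZERO_VAR_REL * scale) & (vy <= _ZERO_VAR_REL * scale)
    denom = vx + vy + (mx - my) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ccc = np.where(undefined, np.nan, 2.0 * cov / denom)
        pearson = np.where(
            (vx > 0) & (vy > 0), cov / np.sqrt(vx * vy), np.nan
        )
    table = pd.DataFrame(
        {
            "feature": list(a.data.columns),
            "family": list(a.families),
            "ccc": ccc,
            "pearson": pearson,
            "mu_i": mx,
            "mu_j": my,
            "sigma_i": np.sqrt(vx),
            "sigma_j": np.sqrt(vy),
        }
    )
    return CCCResult(
        table=table,
        matrix_pair=(a.matrix_size, b.matrix_size),
        tissue=a.tissue,
        mode=a.mode,
        normalization=a.normalization,
        n_subjects=a.data.shape[0],
    )


def neighboring_pairs(matrix_sizes) -> list[tuple[int, int]]:
    sizes = sorted(matrix_sizes)
    return list(zip(sizes[:-1], sizes[1:]))


def all_pairs(matrix_sizes) -> list[tuple[int, int]]:
    return list(itertools.combinations(sorted(matrix_sizes), 2))


@dataclass
class TransitionReport:
    """Family-averaged and overall mean ρc per matrix pair for one
    (tissue, mode, normalization) stratum."""

    table: pd.DataFrame  # pair_lo, pair_hi, family, mean_ccc, n_defined, n_excluded
    tissue: str
    mode: str
    normalization: str
    scope: str

    def overall(self) -> pd.DataFrame:
        """One row per pair: mean ρc over all defined features."""
        return (
            self.table[self.table["family"] == "ALL"]
            .set_index(["pair_lo", "pair_hi"])
            .sort_index()
        )

    def family_means(self) -> pd.DataFrame:
        return self.table[self.table["family"] != "ALL"]

    def mean_change(self) -> float:
        """Mean |Δ(average ρc)| over consecutive neighboring transitions."""
        ov = self.overall()
        steps = [
            (lo, hi)
            for (lo, hi) in ov.index
            if (lo, hi) in neighboring_pairs({p for t in ov.index for p in t})
        ]
        vals = [ov.loc[p, "mean_ccc"] for p in sorted(steps)]
        if len(vals) < 2:
            raise ValueError("need at least two neighboring transitions")
        return float(np.mean(np.abs(np.diff(vals))))


def aggregate_transitions(
    results: list[CCCResult], scope: str = "neighboring"
) -> TransitionReport:
    """Aggregate per-feature ρc into family means and the overall mean
    (each defined feature contributing once) for every required pair.

    ``neighboring``: the one-step pairs of the sizes present;
    ``all_pairs``: every unordered pair.  Undefined features are excluded
    from means and counted.
    """
    if not results:
        raise ValueError("no CCC results given")
    ref = results[0]
    for r in results[1:]:
        if (r.tissue, r.mode, r.normalization) != (
            ref.tissue,
            ref.mode,
            ref.normalization,
        ):
            raise ValueError("results mix tissue/mode/normalization strata")
    by_pair = {tuple(sorted(r.matrix_pair)): r for r in results}
    sizes = sorted({s for p in by_pair for s in p})
    if scope == "neighboring":
        required = neighboring_pairs(sizes)
    elif scope == "all_pairs":
        required = all_pairs(sizes)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    missing = [p for p in required if p not in by_pair]
    if missing:
        raise ValueError(f"missing CCC results for pairs: {missing}")

    rows = []
    for lo, hi in required:
        t = by_pair[(lo, hi)].table
        defined = t.dropna(subset=["ccc"])
        rows.append(
            {
                "pair_lo": lo,
                "pair_hi": hi,
                "family": "ALL",
                "mean_ccc": float(defined["ccc"].mean()),
                "n_defined": int(len(defined)),
                "n_excluded": int(len(t) - len(defined)),
            }
        )
        for fam, sub in t.groupby("family", sort=False):
            fdef = sub.dropna(subset=["ccc"])
            rows.append(
                {
                    "pair_lo": lo,
                    "pair_hi": hi,
                    "family": fam,
                    "mean_ccc": float(fdef["ccc"].mean()) if len(fdef) else np.nan,
                    "n_defined": int(len(fdef)),
                    "n_excluded": int(len(sub) - len(fdef)),
                }
            )
    return TransitionReport(
        table=pd.DataFrame(rows),
        tissue=ref.tissue,
        mode=ref.mode,
        normalization=ref.normalization,
        scope=scope,
    )
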