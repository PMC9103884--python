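"""Assemble the full family-tagged feature vector for one ROI (2D slice)
or one 5-slice ROI volume (3D subset)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..roi import quantize_roi
from .autoregressive import ar_features
from .firstorder import histogram_features
from .gabor import gabor_features
from .glcm import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    GLCM_STAT_NAMES as GLCM_STATS,
    glcm,
    glcm_features,
)
from .gradient import bbox_crop, gradient_features
from .hog import hog_features
from .registry import GLCM_DISTANCES, feature_registry
from .rlm import rlm_features
from .wavelet import haar_features

__all__ = ["FeatureConfig", "FeatureVector", "extract_all", "average_over_slices"]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the extraction step."""

    n_gray_levels: int = 64
    quantization_mode: str = "minmax"


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    families: list[str]
    mode: str

    def __post_init__(self):
        if len(self.values) != len(self.names) or len(self.names) != len(
            self.families
        ):
            raise ValueError("values/names/families length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families:
            counts[fam] = counts.get(fam, 0) + 1
        return counts


def _wrap(family: str, exc: Exception) -> Exception:
    return type(exc)(f"[{family}] {exc}")


def extract_all(
    roi_image: np.ndarray,
    mask: np.ndarray,
    mode: str = "2D",
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Compute every feature family on one ROI in canonical registry order.

    2D mode: GLCM (220) + GRLM (20) + GRA (5) + ARM (5) + DWT (16) +
    HIST (9) + GAB (24) + HOG (8) = 307 values.  3D mode (5-slice volume):
    GLCM over 13 offsets (715) + GRLM (65) + GRA (5) + HIST (9) = 794.
    """
    if config is None:
        config = FeatureConfig()
    img = np.asarray(np.ma.getdata(roi_image), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("mask/image shape mismatch")
    if mask.any():  # crop to bounding box: identical features, less work
        img, mask = bbox_crop(img, mask)
    if mode == "2D":
        if img.ndim != 2:
            raise ValueError("2D mode requires a 2D ROI image")
        directions = tuple(DIRECTIONS_2D)
    elif mode == "3D":
        if img.ndim != 3:
            raise ValueError("3D mode requires a slice-stacked ROI volume")
        directions = tuple(DIRECTIONS_3D)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    values: dict[str, float] = {}
    try:
        q = quantize_roi(
            img, mask, n_levels=config.n_gray_levels, mode=config.quantization_mode
        )
        for d in directions:
            for dist in GLCM_DISTANCES:
                try:
                    feats = glcm_features(glcm(q, d, dist))
                except ValueError as exc:
                    if mode == "3D" and "no valid pixel pairs" in str(exc):
                        # thin volumes cannot realize large through-plane
                        # offsets (e.g. 5 slices, z-distance 5): flag NaN
                        feats = {stat: float("nan") for stat in GLCM_STATS}
                    else:
                        raise
                for stat, v in feats.items():
                    values[f"glcm_{stat}_{d}_d{dist}"] = v
    except ValueError as exc:
        raise _wrap("GLCM", exc) from exc
    try:
        for d in directions:
            for stat, v in rlm_features(q, d).items():
                values[f"rlm_{stat}_{d}"] = v
    except ValueError as exc:
        raise _wrap("GRLM", exc) from exc
    try:
        for stat, v in gradient_features(img, mask).items():
            values[f"gra_{stat}"] = v
    except ValueError as exc:
        raise _wrap("GRA", exc) from exc
    if mode == "2D":
        try:
            for stat, v in ar_features(img, mask).items():
                values[f"arm_{stat}"] = v
        except ValueError as exc:
            raise _wrap("ARM", exc) from exc
        try:
            for stat, v in haar_features(img, mask).items():
                values[f"dwt_en_{stat}"] = v
        except ValueError as exc:
            raise _wrap("DWT", exc) from exc
    try:
        for stat, v in histogram_features(img, mask).items():
            values[f"hist_{stat}"] = v
    except ValueError as exc:
        raise _wrap("HIST", exc) from exc
    if mode == "2D":
        try:
            for stat, v in gabor_features(img, mask).items():
                values[f"gab_{stat}"] = v
        except ValueError as exc:
            raise _wrap("GAB", exc) from exc
        try:
            for stat, v in hog_features(img, mask).items():
                values[f"hog_{stat}"] = v
        except ValueError as exc:
            raise _wrap("HOG", exc) from exc

    registry = feature_registry(mode)
    missing = [name for name, _ in registry if name not in values]
    if missing:
        raise RuntimeError(f"extraction produced no value for: {missing[:5]}")
    return FeatureVector(
        values=np.array([values[name] for name, _ in registry], dtype=float),
        names=[name for name, _ in registry],
        families=[fam for _, fam in registry],
        mode=mode,
    )


def average_over_slices(vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise arithmetic mean of per-slice feature vectors."""
    if not vectors:
        raise ValueError("need at least one feature vector")
    first = vectors[0]
    for v in vectors[1:]:
        if v.names != first.names or v.mode != first.mode:
            raise ValueError("feature vectors have mismatching names or mode")
    stacked = np.stack([v.values for v in vectors])
    return FeatureVector(
        values=stacked.mean(axis=0),
        names=list(first.names),
        families=list(first.families),
        mode=first.mode,
    )
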