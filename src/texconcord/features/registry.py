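"""Canonical, versioned feature-name registry.

The 2D feature set has 307 entries in frozen order — family (GLCM, GRLM,
GRA, ARM, DWT, HIST, GAB, HOG), then statistic, then direction, then
distance/scale — so CSV columns are stable across runs and releases.  The
3D subset (794 entries) covers GLCM over the 13 unique 3D offsets, GRLM
over 13 directions, the 3D gradient family and the histogram family.
"""

from __future__ import annotations

import json

from .autoregressive import AR_STAT_NAMES
from .firstorder import HISTOGRAM_STAT_NAMES
from .gabor import GABOR_ORIENTATIONS_DEG, GABOR_SIZES
from .glcm import DIRECTIONS_2D, DIRECTIONS_3D, GLCM_STAT_NAMES
from .gradient import GRADIENT_STAT_NAMES
from .hog import N_HOG_BINS
from .rlm import RLM_STAT_NAMES
from .wavelet import N_WAVELET_SCALES, WAVELET_BANDS

__all__ = [
    "REGISTRY_VERSION",
    "GLCM_DISTANCES",
    "feature_registry",
    "feature_names",
    "family_counts",
    "registry_json",
]

REGISTRY_VERSION = "1"

GLCM_DISTANCES = (1, 2, 3, 4, 5)


def feature_registry(mode: str = "2D") -> list[tuple[str, str]]:
    """Ordered (name, family) pairs for the requested mode."""
    entries: list[tuple[str, str]] = []
    if mode == "2D":
        dirs = tuple(DIRECTIONS_2D)
        for stat in GLCM_STAT_NAMES:
            for d in dirs:
                for dist in GLCM_DISTANCES:
                    entries.append((f"glcm_{stat}_{d}_d{dist}", "GLCM"))
        for stat in RLM_STAT_NAMES:
            for d in dirs:
                entries.append((f"rlm_{stat}_{d}", "GRLM"))
        for stat in GRADIENT_STAT_NAMES:
            entries.append((f"gra_{stat}", "GRA"))
        for stat in AR_STAT_NAMES:
            entries.append((f"arm_{stat}", "ARM"))
        for band in WAVELET_BANDS:
            for s in range(1, N_WAVELET_SCALES + 1):
                entries.append((f"dwt_en_{band}_s{s}", "DWT"))
        for stat in HISTOGRAM_STAT_NAMES:
            entries.append((f"hist_{stat}", "HIST"))
        for ang in GABOR_ORIENTATIONS_DEG:
            for size in GABOR_SIZES:
                entries.append((f"gab_mag_s{size}_{ang}", "GAB"))
        for k in range(N_HOG_BINS):
            entries.append((f"hog_bin{k}", "HOG"))
    elif mode == "3D":
        dirs3 = tuple(DIRECTIONS_3D)
        for stat in GLCM_STAT_NAMES:
            for d in dirs3:
                for dist in GLCM_DISTANCES:
                    entries.append((f"glcm_{stat}_{d}_d{dist}", "GLCM"))
        for stat in RLM_STAT_NAMES:
            for d in dirs3:
                entries.append((f"rlm_{stat}_{d}", "GRLM"))
        for stat in GRADIENT_STAT_NAMES:
            entries.append((f"gra_{stat}", "GRA"))
        for stat in HISTOGRAM_STAT_NAMES:
            entries.append((f"hist_{stat}", "HIST"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return entries


def feature_names(mode: str = "2D") -> list[str]:
    return [name for name, _ in feature_registry(mode)]


def family_counts(mode: str = "2D") -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, fam in feature_registry(mode):
        counts[fam] = counts.get(fam, 0) + 1
    return counts


def registry_json(mode: str = "2D") -> str:
    """Machine-readable registry documenting every column."""
    payload = {
        "version": REGISTRY_VERSION,
        "mode": mode,
        "features": [
            {"index": i, "name": name, "family": fam}
            for i, (name, fam) in enumerate(feature_registry(mode))
        ],
    }
    return json.dumps(payload, indent=2)
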