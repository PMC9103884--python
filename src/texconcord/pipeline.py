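"""End-to-end orchestration: phantom (or real) images → per-stratum
feature tables → concordance transition reports → quality report.

Slice handling follows the paired study design: in 2D mode the feature
vector of a subject is the element-wise mean over its five slices
(averaging happens *before* concordance); in 3D mode the five slices are
stacked and the 3D feature subset is computed on the volume.  Subjects
with incomplete matrix coverage are dropped with a warning (paired
concordance requires completeness).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tcio
from .concordance import (
    CCCResult,
    FeatureTable,
    TransitionReport,
    aggregate_transitions,
    all_pairs,
    ccc_between_matrices,
)
from .features import (
    FeatureConfig,
    average_over_slices,
    extract_all,
    feature_registry,
    registry_json,
)
from .phantom import (
    DEFAULT_MATRIX_SIZES,
    PhantomSeries,
    build_phantom_series,
)
from .quality import quality_report
from .roi import normalize_roi

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "feature_tables_from_series"]

VALID_MODES = ("2D", "3D")
VALID_NORMALIZATIONS = ("raw", "pm3sigma")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_mode: str = "synthetic"
    manifest_path: str | None = None
    n_subjects: int = 20
    matrix_sizes: tuple[int, ...] = DEFAULT_MATRIX_SIZES
    tissues: tuple[str, ...] = ("bone", "fat", "muscle")
    modes: tuple[str, ...] = ("2D", "3D")
    normalizations: tuple[str, ...] = ("raw", "pm3sigma")
    n_gray_levels: int = 64
    n_slices: int = 5
    fov_mm: float = 200.0
    noise_scale: float = 12.0
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "real"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "real" and not self.manifest_path:
            raise ValueError("real input mode requires manifest_path")
        if not self.modes or any(m not in VALID_MODES for m in self.modes):
            raise ValueError(f"modes must be a subset of {VALID_MODES}")
        if not self.normalizations or any(
            n not in VALID_NORMALIZATIONS for n in self.normalizations
        ):
            raise ValueError(
                f"normalizations must be a subset of {VALID_NORMALIZATIONS}"
            )
        if len(self.matrix_sizes) < 2:
            raise ValueError("need at least two matrix sizes")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("matrix_sizes", "tissues", "modes", "normalizations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    feature_tables: dict[tuple, FeatureTable]  # (tissue, mode, norm, matrix)
    ccc_results: dict[tuple, CCCResult]  # (tissue, mode, norm, lo, hi)
    reports_neighboring: dict[tuple, TransitionReport]  # (tissue, mode, norm)
    reports_all_pairs: dict[tuple, TransitionReport]
    quality: pd.DataFrame
    config: RunConfig
    dropped_subjects: list[str] = field(default_factory=list)

    def tidy_report(self, scope: str = "neighboring") -> pd.DataFrame:
        reports = (
            self.reports_neighboring if scope == "neighboring" else self.reports_all_pairs
        )
        frames = []
        for (tissue, mode, norm), rep in reports.items():
            t = rep.table.copy()
            t.insert(0, "tissue", tissue)
            t.insert(1, "mode", mode)
            t.insert(2, "normalization", norm)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def feature_frame(self) -> pd.DataFrame:
        """All feature tables as one tidy frame (one row per subject ×
        tissue × matrix × mode × normalization)."""
        frames = []
        for (tissue, mode, norm, m), ft in self.feature_tables.items():
            t = ft.data.reset_index(names="subject_id")
            t.insert(1, "tissue", tissue)
            t.insert(2, "matrix_size", m)
            t.insert(3, "mode", mode)
            t.insert(4, "normalization", norm)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _roi_feature_vector(images, mask, mode, normalization, config):
    """Feature vector for one (subject, tissue, matrix) under one mode and
    normalization."""
    def prep(img):
        if normalization == "pm3sigma":
            return np.ma.getdata(normalize_roi(img, mask)).astype(float)
        return np.asarray(img, dtype=float)

    if mode == "2D":
        vectors = [extract_all(prep(img), mask, "2D", config) for img in images]
        return average_over_slices(vectors)
    volume = np.stack([prep(img) for img in images])
    vmask = np.broadcast_to(mask, volume.shape)
    return extract_all(volume, vmask, "3D", config)


def feature_tables_from_series(
    series: PhantomSeries,
    modes=("2D", "3D"),
    normalizations=("raw", "pm3sigma"),
    feature_config: FeatureConfig | None = None,
    tissues=None,
) -> dict[tuple, FeatureTable]:
    """Extract every stratum's subjects × features table from a series."""
    if feature_config is None:
        feature_config = FeatureConfig()
    if tissues is None:
        tissues = series.tissues
    unknown = set(tissues) - set(series.tissues)
    if unknown:
        raise ValueError(f"tissues not present in the series: {sorted(unknown)}")
    tables: dict[tuple, FeatureTable] = {}
    registries = {mode: feature_registry(mode) for mode in modes}
    for tissue in tissues:
        for mode in modes:
            for norm in normalizations:
                for m in series.matrix_sizes:
                    rows, index = [], []
                    for rec in series.subjects:
                        fv = _roi_feature_vector(
                            rec.images[m],
                            rec.rois[tissue][m],
                            mode,
                            norm,
                            feature_config,
                        )
                        rows.append(fv.values)
                        index.append(rec.subject_id)
                    names = [n for n, _ in registries[mode]]
                    fams = [f for _, f in registries[mode]]
                    tables[(tissue, mode, norm, m)] = FeatureTable(
                        data=pd.DataFrame(
                            np.asarray(rows), index=index, columns=names
                        ),
                        matrix_size=m,
                        tissue=tissue,
                        mode=mode,
                        normalization=norm,
                        families=fams,
                    )
    return tables


def _series_from_manifest(manifest_path: str, config: RunConfig):
    """Build an in-memory series-like structure from a real-data manifest."""
    from .phantom import SubjectRecord

    manifest = tcio.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    matrix_sizes = tuple(sorted(int(m) for m in manifest["matrix_sizes"]))
    tissues = tuple(manifest["tissues"])
    subjects, dropped = [], []
    for entry in manifest["subjects"]:
        have = {int(k) for k in entry["matrices"]}
        if not set(matrix_sizes) <= have:
            dropped.append(entry["id"])
            warnings.warn(
                f"subject {entry['id']} lacks matrices "
                f"{sorted(set(matrix_sizes) - have)}: dropped (paired design)",
                stacklevel=2,
            )
            continue
        images: dict[int, list[np.ndarray]] = {}
        rois: dict[str, dict[int, np.ndarray]] = {t: {} for t in tissues}
        for m in matrix_sizes:
            stack, masks = tcio.read_image_stack(entry["matrices"][str(m)], base)
            images[m] = [stack[i] for i in range(stack.shape[0])]
            for t in tissues:
                rois[t][m] = masks[t]
        subjects.append(
            SubjectRecord(
                subject_id=entry["id"], images=images, rois=rois, tissue_configs={}
            )
        )
    if len(subjects) < 2:
        raise ValueError("need at least two complete subjects")
    series = PhantomSeries(
        subjects=subjects,
        matrix_sizes=matrix_sizes,
        tissues=tissues,
        n_slices=int(manifest["n_slices"]),
        fov_mm=float(manifest.get("fov_mm", config.fov_mm)),
        noise_scale=0.0,
        master_seed=config.master_seed,
    )
    return series, dropped


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write all reports under
    ``config.out_dir``.  Deterministic for a fixed config."""
    dropped: list[str] = []
    if config.input_mode == "synthetic":
        series = build_phantom_series(
            n_subjects=config.n_subjects,
            matrix_sizes=config.matrix_sizes,
            master_seed=config.master_seed,
            n_slices=config.n_slices,
            fov_mm=config.fov_mm,
            noise_scale=config.noise_scale,
        )
    else:
        series, dropped = _series_from_manifest(config.manifest_path, config)

    fconfig = FeatureConfig(n_gray_levels=config.n_gray_levels)
    tables = feature_tables_from_series(
        series, config.modes, config.normalizations, fconfig, tissues=config.tissues
    )

    ccc_results: dict[tuple, CCCResult] = {}
    reports_nb: dict[tuple, TransitionReport] = {}
    reports_ap: dict[tuple, TransitionReport] = {}
    for tissue in config.tissues:
        for mode in config.modes:
            for norm in config.normalizations:
                results = []
                for lo, hi in all_pairs(series.matrix_sizes):
                    res = ccc_between_matrices(
                        tables[(tissue, mode, norm, lo)],
                        tables[(tissue, mode, norm, hi)],
                    )
                    ccc_results[(tissue, mode, norm, lo, hi)] = res
                    results.append(res)
                key = (tissue, mode, norm)
                reports_nb[key] = aggregate_transitions(results, "neighboring")
                reports_ap[key] = aggregate_transitions(results, "all_pairs")

    quality = quality_report(series)
    result = PipelineResult(
        feature_tables=tables,
        ccc_results=ccc_results,
        reports_neighboring=reports_nb,
        reports_all_pairs=reports_ap,
        quality=quality,
        config=config,
        dropped_subjects=dropped,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(
        json.dumps(result.config.resolved(), indent=2)
    )
    result.feature_frame().to_csv(out_dir / "features.csv", index=False)
    result.tidy_report("neighboring").to_csv(
        out_dir / "transitions_neighboring.csv", index=False
    )
    result.tidy_report("all_pairs").to_csv(
        out_dir / "transitions_all_pairs.csv", index=False
    )
    result.quality.to_csv(out_dir / "quality.csv", index=False)
    for mode in result.config.modes:
        (out_dir / f"feature_registry_{mode}.json").write_text(registry_json(mode))
    if result.dropped_subjects:
        (out_dir / "dropped_subjects.json").write_text(
            json.dumps(result.dropped_subjects)
        )
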