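"""Image and manifest I/O for the pipeline.

A run's images live on disk as 16-bit PNG (one file per slice) or DICOM,
with 0/255 PNG masks and a JSON manifest mapping subject/matrix/slice/
tissue to file paths.  Intensities are read as stored; DICOM rescale
slope/intercept is applied, nothing else.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantom import PhantomSeries

__all__ = [
    "write_png16",
    "read_image",
    "read_mask",
    "read_image_stack",
    "write_series",
    "read_manifest",
]

PNG16_MAX = 65535


def write_png16(path: Path, image: np.ndarray, lo: float, hi: float) -> None:
    """Store a float image as 16-bit PNG using the affine map
    [lo, hi] -> [0, 65535] (clipping outside)."""
    if hi <= lo:
        raise ValueError("need hi > lo")
    scaled = np.clip((np.asarray(image, float) - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(scaled * PNG16_MAX).astype(np.uint16))


def read_image(path: Path, lo: float | None = None, hi: float | None = None):
    """Read one slice (PNG or DICOM) as float intensities.

    PNG values are mapped back through the manifest's [lo, hi] window when
    given, otherwise returned as stored.  DICOM values have rescale
    slope/intercept applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing slice file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept, int(ds.BitsAllocated)
    arr = iio.imread(path)
    bits = arr.dtype.itemsize * 8
    arr = arr.astype(float)
    if lo is not None and hi is not None:
        arr = lo + arr / PNG16_MAX * (hi - lo)
    return arr, bits


def read_mask(path: Path) -> np.ndarray:
    """Binarize a stored mask at > 0."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing mask file: {path}")
    return np.asarray(iio.imread(path)) > 0


def read_image_stack(manifest_entry: dict, base_dir: Path):
    """Load one (subject, matrix) stack plus its per-tissue masks.

    ``manifest_entry`` schema:
    {"slices": [paths], "masks": {tissue: path}, "window": [lo, hi]}.
    Mixed bit depths within a stack are rejected.
    """
    base_dir = Path(base_dir)
    window = manifest_entry.get("window")
    lo, hi = (window if window else (None, None))
    slices, depths = [], []
    for rel in manifest_entry["slices"]:
        arr, bits = read_image(base_dir / rel, lo, hi)
        slices.append(arr)
        depths.append(bits)
    if len(set(depths)) > 1:
        raise ValueError(f"mixed bit depths within one stack: {sorted(set(depths))}")
    masks = {
        tissue: read_mask(base_dir / rel)
        for tissue, rel in manifest_entry["masks"].items()
    }
    return np.stack(slices), masks


def write_series(series: PhantomSeries, out_dir: Path) -> Path:
    """Export a synthetic series as PNG images + masks + JSON manifest.
    Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # one shared intensity window keeps slices comparable after round-trip
    lo = min(float(img.min()) for rec in series.subjects
             for imgs in rec.images.values() for img in imgs)
    hi = max(float(img.max()) for rec in series.subjects
             for imgs in rec.images.values() for img in imgs)
    manifest: dict = {
        "fov_mm": series.fov_mm,
        "matrix_sizes": list(series.matrix_sizes),
        "tissues": list(series.tissues),
        "n_slices": series.n_slices,
        "subjects": [],
    }
    for rec in series.subjects:
        subj_entry: dict = {"id": rec.subject_id, "matrices": {}}
        for m in series.matrix_sizes:
            mdir = out_dir / rec.subject_id / str(m)
            mdir.mkdir(parents=True, exist_ok=True)
            slice_paths = []
            for si, img in enumerate(rec.images[m]):
                rel = f"{rec.subject_id}/{m}/slice{si}.png"
                write_png16(out_dir / rel, img, lo, hi)
                slice_paths.append(rel)
            mask_paths = {}
            for tissue in series.tissues:
                rel = f"{rec.subject_id}/{m}/mask_{tissue}.png"
                iio.imwrite(
                    out_dir / rel,
                    (rec.rois[tissue][m] * 255).astype(np.uint8),
                )
                mask_paths[tissue] = rel
            subj_entry["matrices"][str(m)] = {
                "slices": slice_paths,
                "masks": mask_paths,
                "window": [lo, hi],
            }
        manifest["subjects"].append(subj_entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_manifest(manifest_path: Path) -> dict:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    return json.loads(manifest_path.read_text())
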