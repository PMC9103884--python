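"""Synthetic multi-subject MR phantom: tissue textures, k-space-truncation
acquisition simulation at several matrix sizes under a fixed FOV, and ROI
masks.

The phantom emulates a shoulder-like study design: three tissue classes of
differing texture complexity — trabecular "bone" (binarized band-pass noise),
blobby "fat" (low-pass noise) and smooth directional "muscle" (anisotropic
low-pass noise) — rendered per subject on five consecutive slices of a
high-resolution 512×512 reference, then acquired at each requested matrix
size by centered Fourier-domain cropping (k-space truncation) plus additive
Gaussian noise whose standard deviation grows as (matrix/reference)², i.e.
noise power ∝ 1/voxel-area.  Small matrices therefore come out blurred and
large matrices noisy, the two phenomena the concordance analysis probes.

All outputs are pure functions of the seeds and configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .roi import scale_roi

__all__ = [
    "AcquisitionSpec",
    "TissuePhantomConfig",
    "SubjectRecord",
    "PhantomSeries",
    "DEFAULT_MATRIX_SIZES",
    "DEFAULT_TISSUE_LAYOUT",
    "default_tissue_configs",
    "generate_tissue_texture",
    "generate_tissue_volume",
    "simulate_acquisition",
    "build_phantom_series",
]

DEFAULT_MATRIX_SIZES = (256, 320, 384, 448, 512)

#: tissue -> (row0, col0, height, width) at the 512 reference matrix.
#: Sized so that ROI pixel counts track clinically reported shoulder ROIs
#: (bone largest, fat smallest).  Regions must not overlap.
DEFAULT_TISSUE_LAYOUT: dict[str, tuple[int, int, int, int]] = {
    "bone": (60, 60, 72, 72),
    "muscle": (320, 80, 56, 56),
    "fat": (60, 320, 52, 52),
}

#: pixels the ROI mask is inset from the tissue-region border (at the
#: reference matrix) to avoid truncation ringing from region edges.
ROI_INSET_PX = 2

_BACKGROUND_INTENSITY = 100.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and noise of one simulated (or real) acquisition."""

    matrix_size: int
    fov_mm: float = 200.0
    slice_thickness_mm: float = 3.0
    noise_scale: float = 0.0
    reference_matrix: int = 512

    def __post_init__(self):
        if self.matrix_size < 32 or self.matrix_size % 2:
            raise ValueError("matrix_size must be an even integer >= 32")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    @property
    def pixel_spacing_mm(self) -> float:
        """In-plane voxel size FOV/matrix, in mm."""
        return self.fov_mm / self.matrix_size


@dataclass(frozen=True)
class TissuePhantomConfig:
    tissue_class: str
    granule_scale_px: float
    directionality: float
    contrast: float
    base_intensity: float
    seed: int = 0

    def __post_init__(self):
        if self.granule_scale_px < 1:
            raise ValueError("granule_scale_px must be >= 1")
        if not 0.0 <= self.directionality <= 1.0:
            raise ValueError("directionality must be in [0, 1]")
        if self.contrast < 0:
            raise ValueError("contrast must be nonnegative")


def default_tissue_configs(seed: int = 0) -> dict[str, TissuePhantomConfig]:
    """Default tissue parameterization.

    Granule scales are a few reference pixels, so texture detail sits near
    the resolution limit of the smallest (256) matrix; muscle is strongly
    directional with low contrast; fat is smooth/blobby; bone is a
    high-contrast binarized trabecular pattern.  Base intensities follow a
    T2-weighted ordering (fat bright, muscle dark).
    """
    return {
        "bone": TissuePhantomConfig("bone", 4.0, 0.1, 90.0, 120.0, seed),
        "fat": TissuePhantomConfig("fat", 6.0, 0.0, 60.0, 170.0, seed),
        "muscle": TissuePhantomConfig("muscle", 5.0, 0.85, 25.0, 70.0, seed),
    }


def _texture_field(
    config: TissuePhantomConfig, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-std (within the field) texture pattern.

    The last two axes are in-plane; a leading axis, if present, is the
    through-plane direction and is smoothed with a sub-slice sigma so
    consecutive slices are correlated but not identical.
    """
    noise = rng.standard_normal(shape)
    g = config.granule_scale_px
    z_sigma = (0.8,) if noise.ndim == 3 else ()
    if config.tissue_class == "bone":
        # band-pass then threshold: trabecular micro-texture primitives
        lo = ndimage.gaussian_filter(noise, sigma=z_sigma + (g / 4.0, g / 4.0))
        hi = ndimage.gaussian_filter(noise, sigma=z_sigma + (g, g))
        band = lo - hi
        binary = (band > np.median(band)).astype(float)
        fieldv = ndimage.gaussian_filter(binary, sigma=z_sigma + (0.6, 0.6))
    elif config.tissue_class == "fat":
        fieldv = ndimage.gaussian_filter(noise, sigma=z_sigma + (g / 2.0, g / 2.0))
    elif config.tissue_class == "muscle":
        # anisotropic low-pass: smooth stripes along the row direction
        s_across = g / 2.0
        s_along = s_across * (1.0 + 10.0 * config.directionality)
        fieldv = ndimage.gaussian_filter(noise, sigma=z_sigma + (s_across, s_along))
    else:
        raise ValueError(f"unknown tissue class {config.tissue_class!r}")
    std = fieldv.std()
    if std > 0:
        fieldv = (fieldv - fieldv.mean()) / std
    return fieldv


def generate_tissue_volume(
    config: TissuePhantomConfig, size: int, n_slices: int
) -> np.ndarray:
    """n_slices × size × size texture volume with through-plane correlation."""
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(config.seed)
    if config.contrast == 0:
        return np.full((n_slices, size, size), config.base_intensity, dtype=float)
    fieldv = _texture_field(config, (n_slices, size, size), rng)
    return config.base_intensity + 0.5 * config.contrast * fieldv


def generate_tissue_texture(config: TissuePhantomConfig, size: int) -> np.ndarray:
    """Single 2D texture slice (deterministic given the config seed)."""
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(config.seed)
    if config.contrast == 0:
        return np.full((size, size), config.base_intensity, dtype=float)
    fieldv = _texture_field(config, (size, size), rng)
    return config.base_intensity + 0.5 * config.contrast * fieldv


def kspace_coefficients(reference_image: np.ndarray, matrix_size: int) -> np.ndarray:
    """Centered k-space crop of the unitary 2D transform, scaled by
    matrix/reference so the DC (mean intensity) level is preserved on
    inverse transform."""
    ref = np.asarray(reference_image, dtype=float)
    n = ref.shape[0]
    m = matrix_size
    f = np.fft.fftshift(np.fft.fft2(ref, norm="ortho"))
    start = (n - m) // 2
    return (m / n) * f[start : start + m, start : start + m]


def simulate_acquisition(
    reference_image: np.ndarray,
    spec: AcquisitionSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Acquire ``reference_image`` at ``spec.matrix_size`` by k-space
    truncation, then add matrix-dependent Gaussian noise.

    The unitary 2D Fourier transform of the reference is cropped centrally
    to matrix × matrix and inverted; the result is scaled by
    matrix/reference so the mean intensity (DC term) is unchanged — images
    at all matrix sizes then share one gray scale, as the noise law (std =
    noise_scale · (matrix/reference)², i.e. SNR ∝ voxel area) presumes.
    No zero-filling interpolation is performed.
    """
    ref = np.asarray(reference_image, dtype=float)
    n = spec.reference_matrix
    if ref.shape != (n, n):
        raise ValueError(
            f"reference image must be {n}×{n}, got {ref.shape}"
        )
    m = spec.matrix_size
    if m > n:
        raise ValueError("upsampling unsupported: matrix_size > reference_matrix")
    if m % 2:
        raise ValueError("odd matrix sizes unsupported")
    coeffs = kspace_coefficients(ref, m)
    out = np.fft.ifft2(np.fft.ifftshift(coeffs), norm="ortho").real
    if spec.noise_scale > 0:
        rng = np.random.default_rng(seed)
        sigma = spec.noise_scale * (m / n) ** 2
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return out


@dataclass
class SubjectRecord:
    """One synthetic subject: per-matrix 5-slice stacks plus per-tissue,
    per-matrix ROI masks (one mask per tissue, shared by all slices)."""

    subject_id: str
    images: dict[int, list[np.ndarray]]
    rois: dict[str, dict[int, np.ndarray]]
    tissue_configs: dict[str, TissuePhantomConfig]


@dataclass
class PhantomSeries:
    subjects: list[SubjectRecord]
    matrix_sizes: tuple[int, ...]
    tissues: tuple[str, ...]
    n_slices: int
    fov_mm: float
    noise_scale: float
    master_seed: int
    layout: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_LAYOUT)
    )

    @property
    def n_images(self) -> int:
        return sum(len(s) for rec in self.subjects for s in rec.images.values())

    @property
    def n_roi_records(self) -> int:
        # one ROI per (subject, matrix, slice, tissue)
        return self.n_images * len(self.tissues)

    def spec(self, matrix_size: int) -> AcquisitionSpec:
        return AcquisitionSpec(
            matrix_size=matrix_size,
            fov_mm=self.fov_mm,
            noise_scale=self.noise_scale,
        )


def _validate_layout(layout: dict[str, tuple[int, int, int, int]], ref: int) -> None:
    items = list(layout.items())
    for name, (r0, c0, h, w) in items:
        if r0 < 0 or c0 < 0 or r0 + h > ref or c0 + w > ref:
            raise ValueError(f"tissue region {name!r} outside image bounds")
    for i, (na, a) in enumerate(items):
        for nb, b in items[i + 1 :]:
            ra0, ca0, ha, wa = a
            rb0, cb0, hb, wb = b
            if ra0 < rb0 + hb and rb0 < ra0 + ha and ca0 < cb0 + wb and cb0 < ca0 + wa:
                raise ValueError(f"tissue regions {na!r} and {nb!r} overlap")


def _roi_mask(
    layout: dict[str, tuple[int, int, int, int]], tissue: str, ref: int
) -> np.ndarray:
    r0, c0, h, w = layout[tissue]
    mask = np.zeros((ref, ref), dtype=bool)
    k = ROI_INSET_PX
    mask[r0 + k : r0 + h - k, c0 + k : c0 + w - k] = True
    return mask


def build_phantom_series(
    n_subjects: int = 20,
    matrix_sizes: tuple[int, ...] = DEFAULT_MATRIX_SIZES,
    tissue_configs: dict[str, TissuePhantomConfig] | None = None,
    master_seed: int = 0,
    n_slices: int = 5,
    fov_mm: float = 200.0,
    noise_scale: float = 12.0,
    jitter: float = 0.1,
    layout: dict[str, tuple[int, int, int, int]] | None = None,
    reference_matrix: int = 512,
) -> PhantomSeries:
    """Render the full synthetic study.

    Each subject receives its own ±``jitter`` (uniform, relative) draw of
    granule scale, contrast and base intensity per tissue — the
    between-subject variance the concordance coefficient requires.  Each of
    the ``n_slices`` reference slices is composited from per-tissue texture
    volumes on a flat background and acquired at every matrix size from the
    same reference slice (paired, within-subject design).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not matrix_sizes:
        raise ValueError("matrix_sizes must be non-empty")
    matrix_sizes = tuple(sorted(matrix_sizes))
    if matrix_sizes[-1] > reference_matrix:
        raise ValueError("matrix sizes must not exceed the reference matrix")
    if tissue_configs is None:
        tissue_configs = default_tissue_configs()
    if layout is None:
        layout = dict(DEFAULT_TISSUE_LAYOUT)
    missing = set(tissue_configs) - set(layout)
    if missing:
        raise ValueError(f"no layout region for tissues: {sorted(missing)}")
    _validate_layout(layout, reference_matrix)
    tissues = tuple(tissue_configs)

    master = np.random.SeedSequence(master_seed)
    subject_seeds = master.spawn(n_subjects)

    base_masks = {t: _roi_mask(layout, t, reference_matrix) for t in tissues}
    roi_by_matrix = {
        t: {m: scale_roi(base_masks[t], reference_matrix, m) for m in matrix_sizes}
        for t in tissues
    }

    subjects: list[SubjectRecord] = []
    for si, sseq in enumerate(subject_seeds):
        jrng = np.random.default_rng(sseq.spawn(1)[0])
        texture_seeds = sseq.generate_state(len(tissues)) % (2**31)
        configs: dict[str, TissuePhantomConfig] = {}
        for ti, t in enumerate(tissues):
            c = tissue_configs[t]
            u = jrng.uniform(1.0 - jitter, 1.0 + jitter, size=3)
            configs[t] = replace(
                c,
                granule_scale_px=max(1.0, c.granule_scale_px * u[0]),
                contrast=c.contrast * u[1],
                base_intensity=c.base_intensity * u[2],
                seed=int(texture_seeds[ti]),
            )
        # one texture volume per tissue, shared across matrix sizes (paired)
        volumes = {
            t: generate_tissue_volume(configs[t], _region_size(layout[t]), n_slices)
            for t in tissues
        }
        noise_rng = np.random.default_rng(sseq.spawn(2)[1])
        images: dict[int, list[np.ndarray]] = {m: [] for m in matrix_sizes}
        for sl in range(n_slices):
            ref = np.full(
                (reference_matrix, reference_matrix),
                _BACKGROUND_INTENSITY,
                dtype=float,
            )
            for t in tissues:
                r0, c0, h, w = layout[t]
                ref[r0 : r0 + h, c0 : c0 + w] = volumes[t][sl, :h, :w]
            for m in matrix_sizes:
                spec = AcquisitionSpec(
                    matrix_size=m,
                    fov_mm=fov_mm,
                    noise_scale=noise_scale,
                    reference_matrix=reference_matrix,
                )
                img = simulate_acquisition(ref, spec, noise_rng)
                images[m].append(img.astype(np.float32))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{si:03d}",
                images=images,
                rois={t: dict(roi_by_matrix[t]) for t in tissues},
                tissue_configs=configs,
            )
        )
    return PhantomSeries(
        subjects=subjects,
        matrix_sizes=matrix_sizes,
        tissues=tissues,
        n_slices=n_slices,
        fov_mm=fov_mm,
        noise_scale=noise_scale,
        master_seed=master_seed,
        layout=dict(layout),
    )


def _region_size(region: tuple[int, int, int, int]) -> int:
    _, _, h, w = region
    return max(h, w, 32)
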