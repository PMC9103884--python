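# Methods

## Problem and design

`texconcord` quantifies how much texture information survives a change of
MR acquisition matrix size under a fixed field of view.  The design is
paired and within-subject: every subject is imaged (or simulated) at each
matrix size, texture features are computed per tissue ROI, and agreement
of each feature across subjects between two matrix sizes is measured with
Lin's concordance correlation coefficient

    ρc = 2·cov(x, y) / (var(x) + var(y) + (μx − μy)²),

using population moments (divisor n).  ρc equals the Pearson correlation
damped by mean- and scale-shift penalties, so |ρc| ≤ |ρ| always; ρc = 1
only for perfect agreement.  Per-feature coefficients are averaged per
family and overall (each defined feature contributing once; an option
weights families equally instead) for every matrix-size transition —
"neighboring" (the four one-step transitions of 256→320→384→448→512) or
all ten unordered pairs.

Degenerate features (zero variance at both matrix sizes) have no defined
ρc; they are excluded from averages and counted, because imputing either
0 or 1 would bias family means.  A feature constant on one side only
evaluates cleanly to ρc = 0 and is kept.

## Acquisition model

A matrix size m at fixed FOV is simulated from a 512×512 reference slice
by centered k-space truncation: the unitary 2D Fourier transform is
cropped to m×m and inverted, then scaled by m/512 so the DC term — the
mean tissue intensity — is unchanged.  Keeping one gray scale across
matrix sizes is what the noise law presumes: additive Gaussian noise with
standard deviation `noise_scale · (m/512)²`, i.e. noise power inversely
proportional to voxel area, so SNR ∝ voxel area.  Gaussian rather than
Rician noise is used because the ROIs are bright, far from the Rician
floor.  No zero-filling interpolation is performed, and no pulse-sequence
(TE/TR/flip-angle) effects are modeled.

Two numerical notes.  First, the centered crop of an even-size spectrum
keeps an asymmetric Nyquist row/column, so the inverse transform has a
tiny imaginary residue that is discarded; Parseval between output energy
and retained-coefficient energy therefore holds to ~1e-7 relative rather
than machine precision.  Second, sharpness comparisons across matrix
sizes are made in physical units (gradient per mm): per-pixel gradients
are not comparable between images with different pixel sizes, because a
larger pixel spacing mechanically inflates per-pixel differences even
when the underlying edge is unchanged.  Per-mm gradient is invariant for
spectral content retained by the crop and strictly reduced by truncation,
which is exactly the blur phenomenon being measured.

## Synthetic phantom

The phantom emulates a shoulder-like study: three tissue classes on five
consecutive slices per subject, rendered at the 512 reference and
acquired at {256, 320, 384, 448, 512} with FOV 200 mm.

* **bone** — thresholded band-pass noise (binarized trabecular pattern);
  granule scale 4 px, contrast 90, base 120.
* **fat** — low-pass Gaussian noise (smooth blobs); granule 6 px,
  contrast 60, base 170.
* **muscle** — strongly anisotropic low-pass noise (smooth directional
  stripes); granule 5 px, directionality 0.85, contrast 25, base 70.

Granule scales of a few reference pixels put the texture detail near the
resolution limit of the 256 matrix, the regime where matrix-size
reduction actually removes texture; base intensities follow a T2-weighted
ordering (fat bright, muscle dark).  `noise_scale = 12` at the 512
reference yields within-ROI SNRs of roughly 2.5–6.5, with muscle darkest
and noisiest.  Texture volumes are filtered in 3D (through-plane σ = 0.8
slices) so consecutive slices are correlated but not identical.

Between-subject variance — without which ρc is undefined — comes from a
±10% uniform jitter of granule scale, contrast and base intensity per
subject and tissue.  Tissue regions are non-overlapping axis-aligned
rectangles on a flat background (intensity 100); ROI masks are the
regions inset by 2 px at the reference, scaled to each matrix by
nearest-neighbor coordinate scaling (area ∝ matrix²).  Region sizes are
chosen so ROI pixel counts track clinically reported shoulder ROIs: bone
68² = 4624 px at 512 and 34² = 1156 px at 256, with muscle and fat
proportionally smaller.

What the phantom does **not** emulate: anatomy (shapes, tissue borders,
partial-volume mixtures), scanner intensity inhomogeneity, Rician noise
statistics, through-plane resolution effects, or patient-level anatomic
diversity beyond the parameter jitter.  Passing trend tests on this
phantom shows the pipeline reproduces the *mechanisms* (blur at small
matrices, noise at large ones, and their effect on feature concordance),
not that it reproduces clinical coefficient values.

## ROI preparation

Statistics are population statistics over in-mask pixels.  The ±3σ
normalization maps μ−3σ → 0 and μ+3σ → 255 with round-half-up and
clipping; its third branch is "0 below the lower bound".  A constant ROI
has no defined normalization and is rejected.  Gray-level quantization
for GLCM/RLM defaults to Ng = 64 levels with per-ROI min–max bounds
(`floor(Ng·(I−min)/(max−min))`, maximum clipped to Ng−1); a full-range
mode uses the bit-depth bounds instead.  Normalization, when enabled,
precedes quantization.  Non-rectangular masks are supported everywhere:
pixel pairs and runs are counted only when every pixel involved is
in-mask, and the 3×3 gradient operators run on a 1-px-eroded mask.

## Feature families (307 in 2D)

| family | count | configuration |
|---|---|---|
| GLCM | 220 | 11 statistics × 4 directions (0°, 45°, 90°, 135°) × distances 1–5 |
| GRLM | 20 | 5 run-length statistics × 4 directions |
| GRA | 5 | moments of 3×3 Sobel magnitude + nonzero fraction |
| ARM | 5 | causal AR θ1–θ4 + residual σ |
| DWT | 16 | Haar sub-band energies, 4 bands × 4 scales |
| HIST | 9 | mean, variance, skewness, kurtosis, P1/P10/P50/P90/P99 |
| GAB | 24 | Gabor magnitude, 4 orientations × 6 envelope sizes |
| HOG | 8 | signed orientation histogram, 8 × 45° bins |

Choices where the classical definitions leave room:

* GLCM matrices are symmetrized and probability-normalized; entropies use
  the natural logarithm with 0·log 0 = 0; sum variance is centered on the
  sum average; difference variance is the variance of the difference
  histogram; correlation of a degenerate (zero-marginal-variance) matrix
  is defined as 0.
* The AR model uses the four causal raster-scan neighbors (left,
  upper-left, upper, upper-right) fit by OLS on mean-subtracted
  intensities; at least 100 pixels with all four neighbors in-mask are
  required.
* Haar energies are mean squared coefficients over positions whose
  support intersects the mask; the bounding box is filled with the
  in-mask mean outside the mask, so a constant ROI has exactly zero
  detail energy.  Band letters are (row-filter, column-filter): LH
  responds to vertical stripes.
* Gabor kernels tie wavelength to envelope (λ = s, σ = s/2, the common
  one-octave convention), are made DC-free, L1-normalized by their
  envelope, and evaluated over a mean-padded bounding box via a shared
  FFT.  Orientation is the carrier direction from +x.
* HOG uses signed orientations over [0°, 360°) in 45° bins weighted by
  Sobel magnitude and normalized to unit sum; an all-flat ROI returns the
  uniform histogram with a warning.
* Percentiles are nearest-rank (smallest value whose CDF reaches p).
* Kurtosis is Fisher (excess); skewness/kurtosis of a constant sample are
  defined as 0.

The 3D subset (794 values on a 5-slice ROI volume) covers GLCM over the
13 unique direction classes of the 26-neighborhood × distances 1–5, GRLM
over the 13 directions, the 3D Sobel gradient family and the histogram
family.  Through-plane offsets that a 5-slice volume cannot realize
(z-distance 5) are flagged NaN and excluded downstream, like any other
undefined feature.  The wavelet, Gabor, HOG and AR families are
2D-only.  In 2D the per-subject vector is the mean over the five slices,
averaged *before* concordance.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| matrix sizes | 256…512 | px | the five acquisition geometries studied |
| FOV | 200 | mm | fixed field of view; pixel spacing = FOV/matrix |
| n_subjects | 20 | — | study size; ρc is estimated across subjects |
| n_slices | 5 | — | consecutive layers averaged (2D) or stacked (3D) |
| noise_scale | 12 | intensity | noise σ at the 512 reference |
| jitter | 0.1 | relative | between-subject parameter variability |
| Ng | 64 | levels | GLCM/RLM quantization depth |
| seed | 0 | — | every random draw flows from one master seed |

## Known limitations

* Texture-analysis tool conventions sometimes quote a 310-feature total
  for this feature set; the enumerable families sum to 307, and the
  package emits exactly those.
* Absolute ρc levels on the phantom depend on the jitter magnitude, which
  stands in for unknowable patient variability; only trends and
  structural/analytic results are asserted.
* The SNR estimator is within-ROI mean/std by default (ROI-only exports
  have no background); a background-region estimator is available but the
  two are not interchangeable numerically.
* Acquisition-time modeling and scanner-specific effects are out of
  scope.

## Problem sizes used in checks

Unit and property tests run on small ROIs (8×8–64×64) against brute-force
oracles.  The trend checks and the acceptance script run the full default
study — 20 subjects × 5 matrices × 3 tissues × 5 slices — in 2D with both
normalizations (the 3D path is exercised on smaller series in the
integration tests; the 2D study is where the trend statements live).
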