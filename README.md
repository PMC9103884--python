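# texconcord

How much texture information survives a change of MR acquisition matrix
size?  `texconcord` answers this with a concordance analysis: the same
subjects are imaged (or simulated) at several matrix sizes under a fixed
field of view, classical texture features are computed per tissue ROI,
and the agreement of each feature across subjects between two matrix
sizes is measured with Lin's concordance correlation coefficient

    ρc = 2·cov(x, y) / (σx² + σy² + (μx − μy)²)

(population moments; ρc = 1 only for perfect agreement, and |ρc| ≤ |ρ|).
Family-averaged and overall ρc per matrix-size *transition*, together
with ROI SNR and gradient sharpness comparators, show which matrix sizes
preserve tissue texture: small matrices blur it away, very large ones
drown it in noise, and the mid-range transitions agree best.

The package is aimed at quantitative-imaging researchers studying
radiomics feature robustness.  It ships:

* a **synthetic phantom** (3 tissue classes — trabecular bone, blobby
  fat, smooth directional muscle — with between-subject variability) and
  a k-space-truncation **acquisition simulator** (blur at small matrices,
  noise growing as the square of matrix size);
* **ROI preparation**: proportional mask scaling, ±3σ intensity
  normalization, gray-level quantization;
* the classical **307-feature 2D texture set** (GLCM 220, run-length 20,
  gradient 5, autoregressive 5, Haar wavelet 16, histogram 9, Gabor 24,
  HOG 8) plus a 794-value 3D subset, all mask-aware;
* **Lin's ρc** per feature, per family and overall for every matrix-size
  pair, stratified by tissue / 2D-3D mode / normalization;
* **SNR and sharpness** reports, CSV/JSON outputs, plots and a CLI.

## Worked example

```python
import texconcord as tc

cfg = tc.RunConfig(n_subjects=8, modes=("2D",), master_seed=1)
res = tc.run_pipeline(cfg)

bone = res.reports_neighboring[("bone", "2D", "raw")].overall()["mean_ccc"]
print(bone.round(3))
print(res.quality[res.quality.tissue == "bone"]
      [["matrix_size", "snr_mean", "sharpness_mean"]].round(2))
```

prints

```
pair_lo  pair_hi
256      320        0.163
320      384        0.291
384      448        0.201
448      512        0.256
Name: mean_ccc, dtype: float64
    matrix_size  snr_mean  sharpness_mean
0           256      2.73          335.54
3           320      2.67          434.94
6           384      2.64          513.18
9           448      2.61          573.84
12          512      2.57          626.81
```

Reading: the bone ROI's average feature concordance is lowest for the
256→320 transition (k-space truncation at 256 removes trabecular
detail), higher in the mid-range; meanwhile SNR falls and sharpness
(mean gradient per mm) rises monotonically with matrix size — the two
opposing quality trends the concordance analysis arbitrates.  At the
full study size (20 subjects) the mid-range advantage for bone and fat
and the spread-reducing effect of ±3σ normalization are stable across
seeds.

The same run from a shell:

```sh
texconcord all --seed 1 --out results/     # writes features.csv,
                                           # transitions_*.csv, quality.csv
texconcord simulate --seed 1 --out phantom/  # PNG slices + masks + manifest
```

Real data can be analyzed by pointing `RunConfig(input_mode="real",
manifest_path=...)` at a JSON manifest of PNG/DICOM slices and 0/255
masks; subjects missing any matrix size are dropped (the design is
paired).

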