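# radstab

**How much does image preprocessing change which radiomic features survive
redundancy removal?**

`radstab` is a tested pipeline for studying the sensitivity of
correlation-based radiomic dimensionality reduction to preprocessing
choices on 2D quantitative maps — the situation of cardiac T1/T2 parametric
mapping, where a single short-axis slice yields a myocardium ROI and a
98-feature radiomic description per subject. Because cohorts of clinical
maps are rarely shareable, the package ships a seeded synthetic-cohort
generator that emulates their statistical structure (annular myocardium-like
ROIs of 740–2370 mm², per-subject pixel spacing in 1.77–2.34 mm, T1-like
≈997 ms or T2-like ≈53 ms intensities with spatially correlated texture),
so every stage is reproducible end to end without any data download.

## The analysis

For a cohort of subjects the pipeline:

1. **Preprocesses** each map: cubic B-spline resampling to an isotropic
   in-plane voxel size (1.8–2.4 mm grid), fixed-bin-width gray-level
   discretization `level(x) = floor((x − min_ROI)/w) + 1` (bin widths chosen
   so every subject has 30–130 levels), and optionally one of 7 filters
   (gradient magnitude, square, square root, stationary Daubechies-3
   wavelet sub-bands LL/LH/HL/HH).
2. **Extracts 98 features** (9 2D shape, 16 first-order, 22 GLCM, 16 GLRLM,
   16 GLSZM, 14 GLDM with α=0, 5 NGTDM; 89 without shape for filtered
   maps), with Chebyshev distance 1 and GLCM/GLRLM direction-averaging over
   {0°, 45°, 90°, 135°}.
3. **Measures collinearity** across subjects: pairwise Pearson (|r| ≥ 0.8)
   or Spearman (|ρ| ≥ 0.9) coefficients, gated at p < 0.05, counting the
   supra-threshold significant pairs ("# of CC").
4. **Eliminates redundant features** iteratively: take the eligible pair
   with the largest |coefficient|, compute each member's mean absolute
   correlation with all other retained features, drop the member with the
   larger mean, repeat until no eligible pair remains.
5. **Quantifies subset stability** across a preprocessing sweep with the
   Nogueira estimator on the binary selection matrix Z (M sweeps × d
   features):

   `index = 1 − mean_f s_f² / ((k̄/d)(1 − k̄/d))`

   where `s_f²` is the unbiased column variance and `k̄` the mean subset
   size; 1 means identical subsets, ≥ 0.5 is conventionally "good", and
   uniformly random subsets score ≈ 0.

Three sweeps mirror the standard experimental design: **Effect A** (voxel
size varies, bin width fixed), **Effect B** (bin width varies, voxel size
fixed) and **Effect C** (filter varies at 2.1 mm and 6 ms / 0.56 ms).

## Worked example

```python
from radstab import (CohortSpec, CollinearityConfig, PreprocessConfig,
                     extract_matrix, generate_cohort, pairwise_correlation,
                     count_supra_threshold, reduce)

spec = CohortSpec(seed=7)          # 26 T1-like subjects
cohort = generate_cohort(spec)

fm = extract_matrix(cohort, PreprocessConfig(target_spacing=2.1, bin_width=6.0))
print("feature matrix:", fm.shape)

corr = pairwise_correlation(fm, CollinearityConfig(method="pearson"))
print("significant |PCC| >= 0.8 pairs:", count_supra_threshold(corr))

red = reduce(corr)
print(f"remaining features: {len(red.remaining)} ({red.percent_remaining_rounded}%)")
```

prints

```
feature matrix: (26, 98)
significant |PCC| >= 0.8 pairs: 483
remaining features: 26 (27%)
```

i.e. at this preprocessing combination 483 of the 4753 feature pairs are
significantly collinear above threshold, and the elimination loop keeps 26
of 98 features (27%). Running the full Effect A sweep and the filter sweep
(Effect C) on the same cohort:

```python
from radstab.runner import run_all_effects, summarize
results = run_all_effects(CohortSpec(seed=7), effects=("A", "C"))
summarize(results, "out/")
```

yields per-bin-width stability indices of 0.54–0.67 (Pearson) and
0.58–0.66 (Spearman) for the voxel-size sweep — all above the 0.5 "good"
mark — but only 0.29/0.30 for the filter sweep: changing the filter
changes *which* features survive far more than changing the voxel size
does, matching the qualitative behaviour reported for real cardiac maps.

The same pipeline is scriptable from the shell:

```bash
radstab simulate --config cohort.yaml --out cohort/ --seed 7
radstab extract --cohort cohort/cohort.json --spacing 2.1 --bin-width 6.0 --out features.csv
radstab reduce --features features.csv --method pearson --out reduction.json
radstab run-effects --config cohort.yaml --out results/ --seed 7
```

## Layout

```
src/radstab/
  cohort.py        synthetic cohorts + NIfTI I/O
  image.py         QuantitativeMap / ROIMask containers
  preprocess.py    resampling, discretization, filters
  features/        98-feature extraction (shape, first-order, 5 texture classes)
  collinearity.py  Pearson/Spearman correlation + significance gating
  reduction.py     iterative correlation-based elimination
  stability.py     Nogueira index, selection frequencies, heatmaps
  runner.py        Effect A/B/C sweeps and report tables
  cli.py           `radstab` console script
docs/methods.md    model, parameters, numerical choices, limitations
```
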