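# Methods

This note documents the models, parameter choices and numerical decisions
behind `radstab`, and what the synthetic cohorts do and do not show about
real quantitative cardiac maps.

## Synthetic cohort model

Each subject is a single-slice 2D map (milliseconds) with an annular ROI
mimicking short-axis myocardium:

- **Pixel spacing**: isotropic, drawn uniformly per subject from
  1.77–2.34 mm (the in-plane resolution range of typical mapping
  acquisitions).
- **ROI geometry**: a ring between radii `r = 0.55 R` and `R`, with `R`
  solved from a target area drawn uniformly within 740–2370 mm². An
  80 mm² sampling margin keeps the pixelised area inside the configured
  bounds; a zero-width area range is therefore not exactly attainable on a
  lattice. The ring is 4-connected by construction for all feasible areas.
- **Intensities**: subject mean = cohort mean (997 ms T1-like, 53 ms
  T2-like) plus a Gaussian between-subject offset; within the ROI a
  spatially correlated zero-mean texture is added, realised as white
  Gaussian noise smoothed by a Gaussian kernel of width equal to the
  correlation length (default 3 mm) and rescaled to the requested SD.
  Background is fixed at 40% of the cohort mean so filters see a real
  edge at the ROI border.
- **Texture support margin**: the textured tissue extends 3 pixels beyond
  the ROI. Without this, B-spline interpolation at ROI-border pixels
  blends with the distant background and inflates the ROI intensity range
  severalfold — an artifact of a hard synthetic edge, not a property of
  tissue. With the margin, the border behaves like a partial-volume
  transition and the discretization level counts stay physiological.
- **Noise defaults**: no within-ROI or between-subject SD is established
  for real cohorts, so the defaults — T1-like (between 50, within 60) ms,
  T2-like (3, 4.5) ms — were fixed once by the level-count rule the
  analysis itself imposes: across the full default sweeps (voxel sizes
  1.8–2.4 mm; bin widths 3.60–6.40 ms T1 / 0.49–0.57 ms T2) every subject
  must land within 30–130 quantization levels. Both defaults satisfy that
  constraint with margin (T1-like 38–118 levels, T2-like 32–65 across the
  default grids).
- **Determinism**: each subject's RNG stream derives from
  `(seed, subject_index)`, so cohorts are pure functions of their spec and
  order-independent.

What the generator does **not** emulate: MRI acquisition physics (MOLLI /
TrueFISP signal models), pathology-dependent spatial patterns (focal
fibrosis, edema), segmentation variability, multi-slice geometry, or
anisotropic native spacing. Passing tests therefore demonstrate the
correctness and internal behaviour of the pipeline under controlled
texture statistics — not clinical conclusions about any patient group.

## Preprocessing

- **Resampling**: cubic B-spline (map) and nearest-neighbour (mask), with
  the output grid origin aligned to the input origin and output size
  `ceil(size × spacing / target)` per axis. Resampling to the native
  spacing short-circuits to the identity. Nearest-neighbour keeps the mask
  binary; a resampled ROI below 9 pixels is an error.
- **Discretization**: fixed bin width,
  `level(x) = floor((x − min_ROI)/w) + 1`, minimum taken over the ROI of
  the (possibly filtered) image being discretized. Filtered maps reuse the
  same bin width as the unfiltered analysis by default; since the square
  and square-root outputs are rescaled to the original intensity range
  (below), the bin width keeps comparable semantics across filters.
- **Filters**: gradient = spacing-aware central-difference magnitude;
  square / square root = pointwise transform followed by a linear rescale
  back to the original min–max range (disable with
  `rescale_power_filters=False`); wavelets = single-level stationary
  (undecimated) Daubechies-3 sub-bands, so filtered maps keep the original
  grid and the mask applies unchanged. Sub-band letters are ordered
  horizontal-then-vertical (LH = low-pass horizontal, high-pass vertical).
- **Wavelet boundary**: periodic (`wrap`) by default rather than symmetric
  padding, because the orthonormal analysis/synthesis identity
  (|H|² + |G|² = 2 per axis) then holds exactly and the four sub-bands
  reconstruct the input to machine precision — a property the test suite
  asserts. Symmetric (`mirror`) padding is available via
  `wavelet_boundary` for users who prefer edge behaviour over exact
  reconstruction.

## Feature set

98 features in seven classes (9 shape / 16 first-order / 22 GLCM /
16 GLRLM / 16 GLSZM / 14 GLDM / 5 NGTDM), 89 without the shape class for
filtered maps. The per-class rosters are frozen in
`features/manifest.py`; two rosters are genuine package choices:

- the 14 first-order intensity statistics (Energy, Kurtosis, Maximum,
  Mean, MeanAbsoluteDeviation, Median, Minimum, Percentile10/90, Range,
  RobustMeanAbsoluteDeviation, RootMeanSquared, Skewness, Variance), plus
  histogram Entropy and Uniformity computed on the discretized levels;
- the 22 GLCM features: the standard 24-member catalogue minus SumAverage
  (identical to JointAverage for symmetric matrices) and MCC.

Conventions worth noting:

- **Kurtosis** uses the Pearson (non-excess) convention, i.e. excess
  kurtosis + 3, matching common radiomics software behaviour; the offset
  is asserted exactly in tests.
- **Direction handling**: GLCM and GLRLM matrices are built per 2D angle
  (0°, 45°, 90°, 135°) at Chebyshev distance 1, features evaluated per
  direction and averaged. GLCMs are symmetrised. A direction with no
  valid pixel pair is excluded from the average.
- **GLDM** dependence counts include the centre pixel
  (j = 1 + #neighbours with |Δlevel| ≤ α, default α = 0), which keeps the
  small-dependence emphasis features finite without special-casing.
- **Degenerate ROIs**: on a single-level ROI, features with vanishing
  denominators (GLCM Correlation, InverseVariance, first-order
  Skewness/Kurtosis, …) are returned as NaN, logged, and later excluded
  pairwise from the correlation analysis instead of being imputed.
- **Shape**: boundary quantities use the 0.5 level-set contour of the
  mask indicator lightly smoothed with a Gaussian (σ = 0.8 px). The raw
  marching-squares polygon overestimates perimeters of digitised smooth
  shapes by ~5–7% (staircase bias), which would bias Sphericity; with
  smoothing a radius-20 disc scores Sphericity within 2% of 1. Mesh
  surface sums signed contour areas, so ring cavities are subtracted and
  their boundaries counted in the perimeter.

## Collinearity, elimination, stability

- Pearson coefficients use the product-moment formula; Spearman = Pearson
  on mid-ranks. Two-sided p-values use the t approximation with n − 2
  degrees of freedom for both methods (the exact small-sample null of the
  Spearman statistic is not used; a seeded permutation scheme is available
  via `p_method="permutation"`). Zero-variance or NaN columns yield
  undefined entries, never counted as significant.
- Default thresholds: |PCC| ≥ 0.8, |SCC| ≥ 0.9, α = 0.05, no
  multiple-testing correction (deliberately, to match common practice in
  correlation-based radiomic reduction).
- The elimination loop gates pair eligibility on *significant and
  supra-threshold* by default; `gate_significance=False` switches to
  threshold-only eligibility. Both modes are recorded in run manifests.
  Mean absolute correlations are computed over currently retained features
  only, excluding undefined entries; correlations are never recomputed
  from data as the set shrinks. Ties break on the canonical feature order
  (class order, alphabetical within class): the earliest pair wins
  selection and the later-ordered member is removed, making the procedure
  fully deterministic.
- The stability estimator uses unbiased (M − 1) column variances. Its
  range is (−1, 1] in practice — it can be negative for anti-consensus
  selections even though it is often described as a [0, 1] quantity; the
  raw value is reported without clipping, with ≥ 0.5 flagged as "good".

## Experiment runner

Effect A groups combinations by bin width (M = 7 voxel sizes per group),
Effect B by voxel size (M = 9 bin widths), Effect C is a single group over
the 8 filter variants at 2.1 mm and 6 ms (T1-like) / 0.56 ms (T2-like).
Effect C runs the correlation analysis on the 89 non-shape features for
every row — including the unfiltered one — so that subsets are comparable
across filters, and its single stability index is computed over the 8
filter subsets. Feature matrices are cached per (voxel size, bin width,
filter), so Effects A and B share their 63-combination grid and switching
correlation method costs no re-extraction. Report tables follow the
conventional layout: supra-threshold counts and integer percentages per
combination, stability to two decimals, full precision in the JSON
manifest. A failed combination is logged and skipped; its sweep group is
still evaluated if at least two rows survive.

Default problem sizes — 26 subjects on an 80×80 grid — keep the complete
default A+B+C sweep with both methods at roughly half a minute on one CPU
while exercising every code path at the full factorial design.

## Known limitations

- The feature rosters aim at the standard radiomics catalogue but are the
  package's own frozen definitions; numerical equality with any specific
  third-party implementation is not asserted.
- Shape boundary quantities depend on the contour smoothing parameter at
  the 1% level; it is a constant of the implementation, not exposed.
- The t-approximation for Spearman p-values is inaccurate for n < 10 with
  heavy ties; use the permutation option for tiny cohorts.
- The stability index is undefined when every combination selects all or
  none of the features; the runner surfaces this as an explicit error
  rather than reporting a clipped value.
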