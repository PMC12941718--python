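# Methods

## Metric definitions and conventions

All metrics are computed on binary per-bone masks resampled to a canonical
600×600 grid. Bones may overlap, so each bone is one raster, not one label
in a shared map. Coordinates are 0-based, `x` along columns, `y` along rows,
with centroids at pixel centers. Units are pixels of the resampled grid
(dimensionless for normalized metrics); no millimetre conversion is
attempted because anisotropic resampling severs the link to the native
pixel pitch.

* **Resampling** is nearest-neighbor (any averaging interpolation would
  break mask binarity), implemented as the explicit pixel-center source-index
  map `src = floor((dst + 0.5) · n_in / n_out)`. This map is idempotent on a
  600×600 input, label-preserving, and exactly testable (the inverse image
  of any source pixel is a computable block). Non-square inputs are
  stretched anisotropically — the normalized metrics are the framework's own
  answer to scale and aspect effects.
* **Binarization** of grayscale inputs is strictly `pixel > 0`:
  deterministic and format-agnostic.
* **OSSD divisor**: the 21 unordered pairs of 7 bones are the complete
  population of pairs, so the population standard deviation (`ddof=0`) is
  the default; the sample convention is exposed as `ossd_ddof=1`.
  Zero-overlap pairs are included.
* **Quantiles** (R50/R90) use linear interpolation at fractional rank
  `q·(n−1)` (the "type 7" convention, numpy's default). The convention is
  recorded in run manifests. R50/R90 reuse the same global centroid `μ` as
  RMSR.
* **Degenerate configurations** (all centroids coincident, `Lbbox = 0`)
  raise an error carrying the raw metrics rather than emitting NaN, so
  cohort runs surface unanalyzable wrists explicitly — mirroring the
  clinical exclusion of severely fused carpi, for which centroid analysis
  is not meaningful.
* The seven default bone labels are the standard carpals minus the pisiform
  (which overlies the triquetrum on a posteroanterior view); labels are
  free-form configuration and carry no semantics.

Geometric properties, all covered by the test suite: translation invariance
of every metric; rotation invariance of the four raw distance metrics (but
*not* of `Lbbox`, which is axis-aligned, so normalized metrics may change
under rotation); scale equivariance of raw metrics and scale invariance of
normalized ones; and the contraction law — mapping
`c_k → μ + (1−λ)(c_k − μ)` multiplies RMSR, MPD, R50, R90 and `Lbbox` by
exactly `(1−λ)`.

## Correlation inference

Pearson's product-moment correlation is the estimator; Fisher-z intervals
(`z_crit = 1.959964`, the exact 0.975 normal quantile) and two-sided t-tests
with `n−2` degrees of freedom provide the interval and p-value. The packaged
reference tables (160 rows of previously reported clinical results at
n ∈ {200, 100, 92, 50, 46}) are reproduced by exactly this construction,
which is diagnostic of the estimator choice: every interval bound is
recovered within ±0.002 of its printed value from the printed `(r, n)`
alone, and every uncensored p-value is consistent with the t-test once the
±0.0005 quantization of a 3-decimal `r` is propagated (the p-value's
sensitivity to r, `|dp/dr| ≈ 9` at n = 200 near r = 0, makes a flat
tighter check impossible from printed inputs). One reference row (the
ΔR50n-vs-ΔTSS interval) is internally inconsistent with its own `(r, n)`
for *any* r at the printed precision and is flagged `inconsistent` in the
CSV; the test suite asserts both that it is the only such row and that the
inconsistency is genuine. Spearman correlation is available as an option.

Reporting rounds r and CI bounds to 3 decimals and p to 4 (half-even). No
multiple-testing correction is applied; each battery CSV records the number
of tests it contains. Pooled designs treat one subject's baseline and
follow-up rows as independent observations — a deliberate simplification
recorded in every `correlate` run manifest.

## Analysis designs

One row per (subject, side, timepoint) is joined from metrics and scores.
Bilateral aggregation **sums** left+right metric values, for symmetry with
the summed bilateral narrowing subscore; mean aggregation is a config
switch. Longitudinal deltas are follow-up minus baseline of the bilateral
sums (the only reading consistent with the reference designs' n = 50 and
n = 46). Total-score designs keep only subjects with the total score present
at both timepoints (listwise deletion), so pooled/per-timepoint/delta
total-score analyses use one consistent subject set. A complete 50-subject
cohort yields n = 200 (all wrists), 100 (per timepoint; per hand pooled),
and 50 (bilateral sums; per hand per timepoint; deltas); a 46-subject
complete-total-score cohort yields 92/46.

## Synthetic phantom generator

The generator emulates the validation study's structure — 50 subjects,
bilateral wrists, two timepoints — with seven ellipse "bones" in a two-row
carpal-like layout on the 600×600 grid, enlarged by a 10 px margin so
neighbouring bones partially overlap at zero severity. A latent severity
`s ∈ [0,1]` per wrist drives:

* **geometry**: anchors contract toward their centroid by
  `λ = λ_max · s` (default `λ_max = 0.5`); bone sizes are unchanged, so
  crowding also increases overlap, qualitatively matching cartilage loss;
* **wrist subscore**: 3 joint sites (the number of summed wrist sites is a
  free parameter) each receive an ordinal grade 0–4 by thresholding `s` at
  (0.2, 0.4, 0.6, 0.8), flipped ±1 with probability 0.1, then summed;
* **total score**: `round(w·K·bilateral_subscore + (1−w)·background)` with
  `w = 0.9`, `K = 4`, and a Gamma(1.2, 80) whole-body background (mean ≈ 96,
  comparable to reported clinical totals) that progresses slowly — the
  independent background attenuates total-score correlations below
  wrist-subscore correlations, reproducing the qualitative clinical ordering.

Severity at baseline is Beta(2, 3) (mild-skewed, as in an established
treated cohort) through a Gaussian copula with between-side correlation 0.7
(symmetric polyarthritis); follow-up adds `|N(0.05, 0.05)|`, truncated at 1,
so damage never regresses. Projection variability is emulated by per-bone
centroid jitter (`σ = 3 px`), a global rotation (`σ = 3°`, clipped to the
documented ±15° range) and global scaling (uniform 0.95–1.05).

Randomness discipline: each purpose (severity, grades, total-score
background, rendering, missingness) draws from its own stream derived from
the master seed, so adding a stage never perturbs earlier stages; every
wrist also carries its own render seed, making cohorts byte-reproducible
and renderable lazily.

What the phantom does **not** model: real bone morphology (ellipses only),
erosions, segmentation-network failure modes beyond centroid jitter,
intensity/texture, or inter-reader score variability. Passing tests
therefore demonstrate correctness of the geometry → metrics → inference
pipeline and recoverability of a known severity link, not clinical effect
sizes: the synthetic severity link is deliberately strong and clean, so
synthetic correlations (≈ −0.9) exceed reported clinical ones (≈ −0.45 to
−0.6).

## Problem sizes and numerical choices

Validation runs use full-size cohorts (50 subjects = 200 rendered wrists,
each 7 ellipses on 600×600; ≈ 2–3 s per cohort) and 20 independent seeds for
parameter recovery; oracle-equivalence checks use 100 random 7-bone mask
sets on 64×64 grids against a pure-Python pixel-list recomputation at 1e−9
relative tolerance. Worked examples are asserted at 1e−12. The end-to-end
contraction check allows 2% for rasterization error (sub-pixel centroid
displacement of discretized ellipses). Parameter recovery asserts the mean
recovered r within ±0.15 of the generating correlation `corr(1−λ, subscore)`
computed on the ground-truth latents.

## Known limitations

* `Lbbox` normalization is projection-dependent (not rotation invariant);
  R90n in particular can correlate positively with narrowing scores, as the
  reference tables also show.
* The battery's pooled designs ignore within-subject correlation; intervals
  there are anti-conservative.
* Severely fused wrists are out of scope by design (excluded, not scored).
* No imputation of missing scores; listwise deletion per design only.
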