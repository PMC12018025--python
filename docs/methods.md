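# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `edubrain`.  Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Exposure construction

Country-level education quality (EQ) is built from PISA-style cycle scores:
subject-domain scores (reading / mathematics / science) are averaged
unweighted within each assessment cycle, cycles are averaged unweighted per
country (countries with missing cycles contribute only the cycles they
have), and the mean is standardized as `EQ = (score − 500)/100 + 2`.  The
shift constant rests on the standard normal keeping 95.4% of its mass
within ±2 SD, so shifted values are essentially always positive.  Domain
weighting is unweighted because no principled weights exist at this level of
aggregation; the aggregation accepts tables with or without a domain column.

Temporal stability is assessed with a mixed linear model
`score ~ year × country` with a random intercept per country (REML,
statsmodels MixedLM).  The joint Wald test over all year×country deviation
slopes gives the stability p-value; the scalar `interaction_coefficient`
reported is the largest-magnitude deviation slope (score points per year).
Zero-variance input short-circuits to coefficient 0 / "stable", since a
zero-residual mixed model cannot be estimated.

Years of education (YoE) is an individual covariate restricted to [0, 20];
rows outside that range (or MMSE outside [0, 30], duplicate ids, unknown
group labels) are rejected at load time with per-row diagnostics.

## Harmonization

Grey-matter maps arrive as masked per-subject voxel vectors (upstream
segmentation and spatial normalization are out of scope).  The second
harmonization step is per-subject min–max scaling to [0, 1]; it is
idempotent and invariant to positive affine intensity transforms, which is
exactly the scanner-gain nuisance it removes.  TIV is never divided out of
voxel values; it is carried as a covariate.

ROI time series are band-pass filtered (0.01–0.1 Hz, second-order
Butterworth applied forward–backward so the filter is zero-phase and
induces no lag structure into connectivity), truncated to the *first* 120
post-filter volumes (subjects with fewer volumes are rejected, never
padded), and z-scored per ROI row.  Gain checks on pure tones (0.05 Hz
retained, 0.2 Hz attenuated >10×) are part of the test suite.

## Network measures

Functional connectivity is the Pearson correlation between ROI rows of the
normalized series.  Graphs are binarized by proportional threshold: the top
`round(0.3 · n(n−1)/2)` edges ranked by *signed* correlation (so negative
edges are effectively excluded at that density; |r| ranking is available),
ties at the cutoff broken by lexicographic (i, j) order for determinism,
self-loops always excluded.  Global efficiency is the mean over ordered node
pairs of 1/d_ij with 1/∞ = 0, computed via unweighted shortest paths; this
average-of-inverses form is well defined on disconnected graphs.  The
literal "inverse of the average shortest path length" variant is available
via `method="inverse_average"` but is not the default, because it is
undefined/degenerate under disconnection and the average-of-inverses is what
standard brain-connectivity toolboxes compute.

## Regional analysis

All units in a map share one design matrix, so the map is fit in a single
pseudoinverse solve; per-unit t statistics for the predictor coefficient use
the usual σ²(XᵀX)⁻¹ form, and the implementation is checked against
per-unit statsmodels OLS to 1e−8.  FDR (Benjamini–Hochberg, q = 0.05) is
applied within each map — per predictor, per modality, per group — never
pooled.  The R² > 0.05 floor is applied to the unadjusted R² of the single
model (predictor + covariates).  Rank-deficient designs fail with the
collinear column names.

The paired comparison of adjusted-R² maps uses the Wilcoxon signed-rank
test (exact for ≤25 nonzero pairs, normal approximation with continuity
correction above; zero differences dropped) and paired Cohen's
d = mean(diff)/SD(diff).  The comparison unit set defaults to the *union* of
floor-passing units of the two predictors (intersection and all-units are
options); a constant shift (SD ≈ 0) reports d = ±∞, and all-zero
differences report "no discrimination" rather than a p-value.

## Whole-brain comparison

The whole-brain outcome (mean GM volume, or global efficiency) is predicted
by ridge regression with the predictor plus covariates; the two compared
models differ only in EQ vs YoE (or EQ×YoE), keeping the contrast
symmetric.  Cross-validation is 3-fold × 20 repetitions; within each outer
training partition the penalty is selected by an inner 3-fold grid search
over 1000 log-spaced alphas in [1e−10, 1e10] (minimum mean validation MSE,
ties to the smaller alpha).  Regressors are z-scored with training-fold
statistics only; the ridge path is solved by SVD so the full alpha grid is
evaluated in one vectorized pass per fold, and agrees with the
scikit-learn ridge solver to 1e−8 and with OLS at the grid minimum to 1e−6.

The point estimate is Δmean = mean R²_EQ − mean R²_YoE over the 20
repetitions (reported ×10⁻² by convention), alongside the ratio
mean R²_EQ / mean R²_YoE (guarded when the denominator is below 1e−6).

**Inference.**  Repetitions reuse the same subjects, so repetition pairs are
*not* exchangeable: the paired differences share a dataset-level offset, and
sign-flipping them is badly anti-conservative under data-level nulls (a
measured false-positive rate of ~0.38 at α = 0.05).  The default
permutation test therefore operates at the subject level: the per-subject
out-of-fold squared-error difference between the two models is sign-flipped
(full enumeration when 2^n fits in the iteration budget, else Monte Carlo
with the add-one correction).  Subjects are the approximately independent
units, and the measured null false-positive rate is ≤0.01–0.05.  The
repetition-level sign-flip remains available (`scheme="reps"`) and is exact
when repetition pairs are genuinely exchangeable draws, e.g. independent
replicates.

The 95% CI is bootstrapped over repetition pairs.  The default is a
studentized bootstrap-t interval: the plain percentile interval is z-like
rather than t-like and measurably undercovers at small repetition counts
(91.0% at 10 repetitions vs 94.4% for bootstrap-t, both at nominal 95%);
percentile remains available via `ci_method="percentile"`.  Note this CI
reflects CV-partition variability conditional on the dataset, not sampling
variability across cohorts.

## Sensitivity battery

* **Interaction**: EQ vs the product EQ×YoE, same machinery.
* **Socioeconomic adjustment**: Gini + GDP (country-level) or SES
  (individual) added to *both* models; the report carries baseline and
  adjusted contrasts and a deterministic verdict — "reversed" if the sign
  flips, "attenuated" if a significant baseline loses significance,
  "robust" otherwise.
* **Leave-one-country-out**: each country's subjects dropped in turn, the
  contrast re-estimated with the same CV settings, and sign/significance
  preservation tabulated; drops leaving fewer than 3k subjects are skipped
  with a flag.
* **Image quality**: Pearson r of SNR/tSNR with each exposure, flagged
  negligible inside (−0.1, 0.1); the outcome is residualized on the quality
  metrics by OLS (a projection, hence idempotent) and the contrast rerun.

## The synthetic cohort

The generator emulates the study conditions, not any particular dataset:

* **Countries**: 20 countries with mean PISA scores spread evenly over
  393–561 — the range that standardizes to EQ 0.93–2.61 with SD ≈ 0.51 —
  each with 4–7 cycles (three randomly chosen countries keep 4, 6 and 5
  cycles, mirroring real participation gaps) and cycle/domain noise of
  8/5 score points.
* **Participants**: groups HC/AD/FTLD (defaults 200/120/80) with age, sex,
  MMSE and YoE drawn from group-specific distributions typical of aging and
  dementia cohort tables; country assignment with log-normal size imbalance.
  YoE is coupled to country EQ through a latent-Gaussian construction at
  r = 0.3 (exposure confounding); T1w SNR is coupled to EQ at r = −0.15,
  fMRI SNR at 0.07 and tSNR at −0.02 — the nuisance pattern the quality
  sensitivity analysis is designed to catch.  SES tracks YoE; Gini and GDP
  are country-level functions of EQ.
* **Grey matter**: voxel value = baseline + group atrophy + planted effects
  + noise on a small grid (default 12³, ellipsoid mask).  Between-subject
  variability is scaled by a tissue-probability profile (4b(1−b))²
  that vanishes at the intensity extremes: real segmentations have
  near-zero variance in background and peak-tissue voxels, which is what
  keeps the per-subject min/max (and hence min–max harmonization) stable.
  Effect sizes are in residual-SD units (default β_EQ = 0.5, β_YoE = 0.25,
  the 2:1 recovery condition).  Topographies are nested: the YoE voxel set
  is a random half of the broader EQ set (default 20% of the mask),
  mirroring the observed regional pattern in which the country exposure's
  influence covers the individual exposure's regions and extends beyond
  them.  With disjoint sets and correlated exposures, YoE would inherit
  EQ's strong voxels at detectable strength and the qualitative
  "more significant units for EQ" pattern would invert.
* **Time series**: latent-factor AR(1) signals (6 factors, φ = 0.6) mixed
  by a block loading matrix, plus shared pair signals on the planted edge
  sets whose amplitude rises with the exposure — connectivity on those
  edges, and through them network integration, tracks EQ/YoE.  No BOLD
  hemodynamics are simulated.

Identical configs (including seed) reproduce cohorts bit for bit; all
internal streams derive from `SeedSequence([seed, stage])`.

What passing tests do *not* show about real data: the generator has no
site/scanner block structure beyond per-subject intensity scale, no spatial
autocorrelation within maps, no motion or physiological artifacts, and its
exposure effects are exactly linear.  Calibration and recovery results are
statements about the pipeline's statistical machinery, not about effect
sizes in any real cohort.

## Problem sizes

Defaults are desk-scale by design: 12³ voxel grids (~900 masked voxels),
90 ROIs, 140 volumes.  The test suite and acceptance script use 500-subject
single-group cohorts for recovery, 90–120-subject cohorts for null
calibration (20 cohorts for FDR calibration, 100–200 for permutation
calibration), and 500 scaled-down replicates (10 repetition pairs, 1000
iterations) for bootstrap coverage.

## Known limitations

* The repetition-level CI quantifies partition noise only; cohort-level
  uncertainty requires subject-level resampling, available behind the
  subject-loss machinery but not the default report.
* The subject-level sign-flip assumes per-subject loss differences are
  approximately independent and symmetric under the null; with very small
  groups or strongly discrete outcomes (tiny graphs) it can be mildly
  miscalibrated.
* Reported sample-size tallies in multi-site aging cohorts are sometimes
  internally inconsistent between text and demographic tables (e.g. an
  rs-fMRI subsample stated as 3204 where the table rows sum to 3013); the
  generator's defaults follow demographic-table-style values and no attempt
  is made to resolve such discrepancies.
* PISA-based EQ is a country-level proxy; nothing in the package addresses
  within-country variation in education quality, and the cross-sectional
  design supports no causal claims.
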