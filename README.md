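# edubrain

Does the *quality* of the education a person grew up with predict their brain
structure and function better than the *number of years* they spent in
school?  `edubrain` implements the statistical machinery for that comparison:
a country-level education-quality exposure (EQ, built from PISA scores)
against individual years of education (YoE) as predictors of grey-matter
volume and resting-state functional-network efficiency, in healthy aging and
dementia cohorts (HC / AD / FTLD).

Because no individual-level data ship with the package, a first-class
synthetic-cohort generator produces all inputs — country score tables,
participant demographics, grey-matter maps, ROI time series — with *known
planted effects*, so every stage of the pipeline is testable end to end and
its calibration and power can be measured against ground truth.

## The model

**Exposure construction.**  Country mean PISA scores (scale mean 500, SD
100) are averaged over available assessment cycles (domains averaged within
a cycle first), then standardized and shifted:

    EQ = (mean PISA − 500) / 100 + 2

The +2 shift removes negative values (a standard normal keeps 95.4% of its
mass within ±2 SD).  Temporal stability of the country scores is checked
with a mixed linear model (`score ~ year × country`, random intercept per
country).

**Regional level.**  For each brain unit *u* (a GM voxel or an FC edge) and
each predictor *x* ∈ {EQ, YoE, EQ×YoE}:

    brain_u = β₀ + β₁ x + γᵀ covariates + ε

by OLS, with covariates age, sex, MMSE, plus TIV (grey matter) or
eyes-open/closed (functional connectivity).  Predictor p-values are
FDR-corrected (Benjamini–Hochberg, q = 0.05) within each map; units with
R² ≤ 0.05 are screened out.  The EQ and YoE adjusted-R² maps
(R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)) are compared with a paired
Wilcoxon signed-rank test and a paired Cohen's d.

**Whole-brain level.**  The whole-brain measures — mean GM volume over the
mask, and the global efficiency E = ⟨1/d_ij⟩ of the FC graph binarized at a
proportional threshold of 0.3 — are predicted by ridge regression
(3-fold CV × 20 repetitions, penalty grid-searched over 1000 log-spaced
values in [1e−10, 1e10] by nested CV).  The two predictors are contrasted
with Δmean = mean R²_EQ − mean R²_YoE, a label-swap permutation p-value, a
bootstrap 95% CI, and the effect ratio mean R²_EQ / mean R²_YoE.

**Sensitivity battery.**  EQ vs the EQ×YoE interaction; re-runs with
country-level (Gini, GDP) and individual (SES) socioeconomic covariates;
leave-one-country-out robustness; image-quality (SNR/tSNR) screening and
GLM residualization.

## Worked example

```python
import edubrain as eb

cfg = eb.SyntheticConfig(n_subjects_per_group=(300, 0, 0), n_rois=4,
                         n_volumes=125, seed=42)
cohort = eb.simulate_cohort(cfg)          # planted beta_EQ : beta_YoE = 2 : 1

spec_eq  = eb.RegressionSpec("eq",  ("age", "sex", "mmse", "tiv"))
spec_yoe = eb.RegressionSpec("yoe", ("age", "sex", "mmse", "tiv"))
map_eq  = eb.fit_mass_univariate(cohort.gm.data, cohort.participants, spec_eq)
map_yoe = eb.fit_mass_univariate(cohort.gm.data, cohort.participants, spec_yoe)
print(f"significant voxels  EQ: {map_eq.q_significant.sum()}   "
      f"YoE: {map_yoe.q_significant.sum()}")

y = eb.whole_brain_mean_volume(cohort.gm)
cv_eq  = eb.cv_ridge_r2(y, cohort.participants, spec_eq,  seed=0)
cv_yoe = eb.cv_ridge_r2(y, cohort.participants, spec_yoe, seed=0)
res = eb.compare_predictors(cv_eq, cv_yoe, iterations=10_000, seed=0)
print(f"whole-brain GM: delta-mean = {100*res.delta_mean:.1f} x 10^-2, "
      f"p = {res.p:.1e}, ratio = {res.ratio:.2f}")
```

prints

```
significant voxels  EQ: 227   YoE: 133
whole-brain GM: delta-mean = 16.4 x 10^-2, p = 1.0e-04, ratio = 1.22
```

EQ flags more voxels than YoE at FDR 0.05, and at the whole-brain level its
cross-validated R² exceeds YoE's by 0.164 (Δmean is conventionally reported
×10⁻²), a ratio of 1.22, with the planted 2:1 effect-size ordering correctly
declared significant.

A CLI wraps the same stages:

```sh
edubrain simulate --out sim/ --seed 1
edubrain eq --pisa pisa.csv --out eq.csv --stability
edubrain network --ts-dir sim/timeseries --out metrics.tsv
edubrain run-all --out results/ --seed 1
```

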