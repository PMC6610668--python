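# Methods

## Scope and data model

The package models the probability of chronic radiation-associated
dysphagia (RAD) — aspiration, stricture, or gastrostomy dependence at
≥ 1 year after head-and-neck chemoradiation — as a function of the dose
delivered to eight non-target swallowing-muscle ROIs (superior/middle/
inferior pharyngeal constrictors, anterior and posterior digastric,
mylo/geniohyoid complex, genioglossus, intrinsic tongue) and of patient
age at treatment. Inputs are plain-text DVHs (two columns, cumulative or
differential, percent or fractional volume autodetected at a 1.5
threshold) and a one-row-per-patient cohort table. DICOM parsing,
segmentation and outcome abstraction are out of scope.

## DVH reduction

A cumulative DVH is differentiated interval-by-interval (bin mass = drop
in cumulative volume; representative dose = interval midpoint, unbiased
for a piecewise-uniform dose density). Differential masses must sum to 1
within 1e-6, so truncated cumulative histograms fail validation rather
than being silently renormalized.

**EQD2.** Each bin dose is converted to its 2-Gy-fraction equivalent
under the linear-quadratic model, `D·(d + α/β)/(2 + α/β)`. The per-bin
fraction size is `d = D / n_fractions` — a uniform-fractionation
assumption across bins, standard for DVH-level correction when no
per-voxel fractionation is available. α/β defaults to 3 Gy
(late-responding muscle) and is configurable; the logging layer records
the value used because downstream constraints inherit it.

**gEUD.** The power mean `(Σ v_i D_i^a)^{1/a}`. The default exponent is
`a = 1` (arithmetic mean dose) because the derived constraints are
stated as mean doses; the exponent is configurable per ROI. `a = 0`
(geometric mean) is rejected rather than special-cased.

## NTCP model and estimation

The outcome model is logistic in the summary dose with additive clinical
covariates; age enters continuously in years (decade strata are a
reporting device only, represented at ages 45/55/65/75). Estimation is
in-package maximum likelihood:

- Newton iterations on a standardized design (continuous columns
  centred/scaled) with step-halving on the deviance; once the gradient
  inf-norm falls below 1e-4 the raw Newton step is taken without a line
  search, because deviance differences near the optimum fall below
  double-precision resolution while the gradient still converges
  quadratically. Convergence tolerance: 1e-8 on the standardized
  gradient inf-norm.
- Separation is reported explicitly (never returned as a huge
  coefficient) on any of three signals: a standardized coefficient
  passing ±50, a deviance still decreasing at the 100-iteration cap, or
  an essentially perfect in-sample fit (deviance < 1e-5). A Nelder–Mead
  restart with Newton polish backs up stalled non-separated fits.
- Probabilities inside likelihoods are clipped to [1e-12, 1 − 1e-12].
- Covariance is the inverse observed information at the MLE; p-values
  are two-sided Wald (normal reference); AUC is the ROC area of the
  fitted linear predictor; `BIC = k ln n − 2 lnL`.

The two-parameter dose–response form at a fixed covariate profile is
`D50 = −(β₀ + Σβ_j x_j)/β_D`, `γ50 = β_D·D50/4`; it requires `β_D > 0`
and raises a non-monotone-response error otherwise.

**Ordinal variant.** Graded outcomes use a proportional-odds
cumulative-logit model, `P(Y ≤ j) = σ(θ_j − η)`, with thresholds kept
strictly increasing by an exponential increment parameterization and a
BFGS search on the standardized design. With two levels it reproduces
the binary fit (`β₀ = −θ₀`). The synthetic generator codes grade as the
number of distinct RAD criteria met (0, 1, 2+) — a modelling choice,
since graded severity data carry no canonical coding here.

**Bootstrap.** Case resampling with replacement at full cohort size,
default B = 2000, percentile intervals and pointwise percentile curve
bands. Replicates that separate or fail to converge are flagged and
excluded from bands; more than 50% failures raises a diagnostic error.
The ensemble is a deterministic function of (seed, cohort).

## Covariate selection and diagnostics

Forward-stepwise search on top of the always-included dose term: at each
step the candidate whose addition lowers BIC most is added; the search
stops when no candidate lowers BIC. Ties break to the earliest-listed
candidate; candidates whose fit fails are excluded with a warning. BIC
(not a p-value threshold) is the criterion throughout the search, while
the per-ROI diagnostics table reports per-coefficient Wald p-values —
chosen over likelihood-ratio p-values because the table is per
coefficient. Dose p-values across the eight ROIs form one
Benjamini–Hochberg family and age p-values another, mirroring the
two-column layout of per-ROI toxicity reporting; the family definition
is configurable by calling `benjamini_hochberg` directly on any vector.

## Constraints and curves

The dose keeping modelled risk at target `p` is the closed-form logistic
inversion, cross-checked against a bisection root find to 1e-6 Gy on
every call. Cells where the zero-dose (baseline) risk already exceeds
the target carry an explicit flag rather than a number. Display follows
the convention of clinical constraint tables: nearest-integer Gy, with
values under the 10 Gy floor shown as `<10`; full precision is retained
in the serialized output. With `β_age > 0` the constraint falls by
exactly `β_age/β_D` Gy per year of age, which the tests verify
analytically. Curves are evaluated per age stratum on a user dose grid,
with bootstrap percentile bands.

## Synthetic data generator

`simulate_cohort` emulates the assumed study structure: n = 300 by
default; decade-of-age mix 19/49/23/9% (uniform ages within 40–50,
50–60, 60–70, 70–80); eight ROI summary doses from truncated normals
whose means differ by muscle (constrictors near target volumes run hot,
floor-of-mouth muscles cooler), jointly spanning ~10–75 Gy; a shared
per-patient dose multiplier (sd 0.10) standing in for the inter-ROI
correlation a single treatment plan induces; clinical covariates at the
study's cohort proportions (91% male, 65% cisplatin, etc.), null with
respect to outcome unless given a coefficient. The outcome is Bernoulli
with logistic probability in the mylo/geniohyoid (driver ROI) dose and
age. Default generating coefficients (β₀ = −8.03, β_D = 0.07/Gy,
β_age = 0.033/yr) were set once so that overall prevalence is ≈ 11%
under the default dose/age distributions and the 45→75 age odds ratio is
≈ 2.7; they are illustrative of the modelled regime, not estimates.
`simulate_dvh` produces sigmoidal cumulative DVHs rescaled to span
volume 1 → 0, with monotonicity-preserving multiplicative jitter on the
differential masses.

What the generator does **not** emulate: real 3-D dose spatial
structure, sub-ROI heterogeneity, realistic inter-ROI correlation beyond
one shared multiplier, covariate–dose confounding (large tumours driving
both dose and risk), or informative follow-up. Passing recovery tests
therefore demonstrate correctness of the estimation and inversion
machinery under the assumed model, not clinical validity of any
particular constraint value — deriving clinic-ready numbers requires a
real patient-level cohort.

## Pipeline and reproducibility

`run_full_analysis` chains cohort parsing, optional DVH reduction,
per-ROI fits (dose + age), stepwise selection, diagnostics, bootstrap,
curves and constraints, writing delimited tables plus a versioned JSON
report. One master seed deterministically derives per-stage seeds (CRC32
stage tags fed to a seed sequence), so a rerun with the same config is
byte-identical. Any stage failure aborts with a stage-labelled error and
removes partial outputs. Problem sizes used in the shipped checks —
n = 300 at study scale, n = 1000–5000 for recovery and consistency
checks, 20 seeds for repeated-run rates, B = 40–200 bootstrap replicates
in tests (B = 2000 as the analysis default) — were chosen as the
smallest sizes at which the statistical checks are stable.

## Known limitations

- The gEUD exponent actually used per muscle in any given study is
  rarely reported; results can be sensitive to it for serial-behaving
  structures. It is exposed per ROI and logged.
- Wald p-values are first-order; for cohorts with few events per
  coefficient, profile-likelihood or exact intervals would be
  preferable.
- The proportional-odds fit reports no analytic covariance; compare
  against `statsmodels` `OrderedModel` when standard errors are needed.
- Constraint cells are point-fit inversions; propagating bootstrap
  uncertainty into the table (reporting, e.g., a conservative band
  edge) is possible via the ensemble but not the default.
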