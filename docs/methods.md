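# Methods

This note documents the models, procedures, and numerical choices behind
`srmquant`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## The quantitation model

Targeted SRM quantitation assumes a locally linear instrument response:
the peak area of an analyte's quantifier transition is proportional to its
concentration over a validated range. Response is expressed as the area
ratio to a stable-isotope-labeled internal standard (ISTD) spiked at a
fixed concentration, which cancels injection-to-injection and
matrix-dependent response variation. Entities without a usable ISTD (in the
builtin panel: creatinine, γ-butyrobetaine, and 3-hydroxybutyrate, whose
labeled-standard signal is not repeatable) are processed on raw areas and
flagged `normalized=False` throughout.

Chromatographically unresolved isomer pairs that share transitions
(Leu+Ile, TDCA+TCDCA, GCDCA+GDCA, ADMA+SDMA) are *co-quantified*: from
ingestion onward they form a single quantification entity with one shared
quantifier transition, one ISTD, one calibration curve, and one reported
concentration. This mirrors how such panels are actually reported — the
instrument cannot attribute the shared signal to either isomer.

### Weighted calibration

Calibration fits response on nominal concentration by weighted least
squares with weights w = 1/x. Proportional (multiplicative) detector noise
makes the response variance grow with concentration; unweighted fitting
would let the highest standards dominate and bias back-calculation at the
low end, which matters most clinically. The fit is the exact closed-form
solution of the two-parameter weighted normal equations (no iterative
optimizer); the weighted R² uses the weighted response mean as the null
model. At least five distinct levels are required; the threshold can be
lowered explicitly per entity for documented few-point cases (analytes
whose detection limit leaves only the top standards usable).

Start- and end-of-sequence series are pooled into one fit by default. An
alternative (averaging two separate fits) was considered and rejected: with
equal level sets the pooled fit uses the same information with fewer moving
parts, and pooling makes replicate counts per level explicit in the
accuracy checks.

### LOD

The limit of detection is the lowest standard level whose **median** S/N
across replicate series reaches 3. The median (rather than mean or minimum)
makes the estimate robust to a single noisy injection while still requiring
the typical injection to qualify. If the lowest measured level already
qualifies, the LOD is reported as a below-lowest flag ("< 2.5" when 2.5
ng mL⁻¹ is the lowest standard) — the data cannot localize it further; if
no level qualifies, an above-highest flag is reported.

### Linear range

The validated range (LLOQ–ULOQ) is found by exhaustive scan over all
contiguous runs of at least `min_points` levels: a run qualifies when the
fit restricted to it back-calculates **every** level's mean response within
the 80–120% accuracy band; the longest qualifying run wins. Ties break
toward the lower starting level (favoring sensitivity at the low end), then
the lower top level — a fixed, documented rule so results are deterministic.
Accuracy is judged on the back-calculated mean response per level rather
than per individual replicate; with two pooled series per level this keeps
single-replicate outliers from vetoing an otherwise accurate level while
still being a per-level criterion. With 19 levels the scan examines at most
120 runs, so exhaustiveness costs nothing.

Back-calculated concentrations are flagged against the curve: below the LOD
(or non-positive) → `below_lod`, no value reported; between LOD and LLOQ →
`below_lloq` with the value retained (downstream detection filtering needs
to know the analyte was seen); above ULOQ → `above_uloq` with the value
retained. Technical replicates are quantified independently — averaging is
deferred to the mixed model, which needs replicate-level data.

## Repeatability

%RSD = 100·sd/mean with the sample (n−1) standard deviation, appropriate
for the small QC sets (4 intra-day, 15 inter-day injections). Inter-day
%RSD pools all 15 injections rather than averaging daily means, so the
reported n is the total injection count. The report keeps the three QC
levels separate; any level-dependent pooling is left to the reader of the
report, and entities missing a QC level are omitted with a logged warning.

## Balanced subsample selection

Selection is a pure random search: `n_draws` stratified subsamples (k per
group, uniform without replacement within group, via the k-smallest-keys
construction), each scored by the maximum |Pearson r| between any clinical
covariate and the 0/1 group indicator; the minimizing draw wins, ties
broken by draw order. Binary covariates are encoded 0/1 before correlating
(a point-biserial/φ-type coefficient). A covariate constant within a draw
cannot confound the comparison, so it scores r = 0 with a degeneracy flag
rather than poisoning the draw with an undefined value. Draws are **not**
deduplicated — duplicates are wasteful but harmless to correctness, and
deduplication would change the uniform-draw semantics. Each draw consumes a
contiguous block of the seeded random stream, so the best score over the
first m draws is a well-defined, non-increasing function of the draw budget
and is invariant to the internal chunk size of the vectorized scorer.
Defaults are k = 25 per group and 10⁶ draws.

## Association

Metabolites detected (any replicate above LOD) in strictly more than 70% of
samples enter the analysis. Per metabolite, a linear mixed model is fit by
REML: log₁₀ concentration on the clinical fixed effects with a random
intercept per participant capturing the correlation among that
participant's replicate injections. The log₁₀ response is the default
because concentration effects in this setting are multiplicative and the
downstream network strength scale is log10-based; a raw-scale option
exists. Below-LLOQ values enter as reported (censoring or imputing them
would discard exactly the low-abundance signal the detection filter was
designed to protect); below-LOD rows are excluded row-wise. Wald two-sided
tests per coefficient are used as-is — no empirical-Bayes variance
moderation or replicate-correlation shrinkage is applied, a deliberate
simplification relative to moderated-statistics workflows.

Two degenerate-input rules: (a) a rank-deficient fixed-effect design raises
an error listing the aliased terms (left-to-right greedy rank scan);
(b) when the fixed effects fit the response essentially exactly (pooled OLS
residual variance < 1e-12), REML's variance components are unidentified, so
the model returns the exact OLS coefficients with p = 0 instead of a
spurious non-convergence.

Benjamini–Hochberg step-up correction is applied per fixed-effect term
across metabolites (not across terms); the family size m — the number of
converged metabolite models — is recorded in the output (`bh_m`).
Non-converged fits are excluded from the BH family but remain listed.
Significant coefficients (adjusted p < 0.05) become bipartite edges with
sign from the coefficient, strength = log₁₀|coefficient| (rescaled linearly
to a plotting width), and a highlight flag on the two key study terms
(group and eGFR).

## The synthetic-data generator

The generator emulates the statistical structure the analysis chain
assumes, with full ground truth:

* **Area noise**: area = rf·c·(1+ε_prop) + ε_base with Gaussian ε. The
  proportional term produces the heteroscedasticity that motivates 1/x
  weighting; the additive term produces finite S/N values, hence finite
  LODs and a noise-limited LLOQ. S/N is reported as area/baseline_sd.
  Defaults: response factor 100 area units per ng mL⁻¹, proportional CV 5%,
  baseline SD 500 area units (LOD in the tens of ng mL⁻¹), ISTD CV 3%
  (30% for the unstable-ISTD entities).
* **Calibration series** at the 19 levels 2.5–75,000 ng mL⁻¹, emitted twice
  (sequence start and end), plus blank injections.
* **QC study**: 4 intra-day runs plus 3 runs × 5 days with a per-day
  multiplicative shift (CV 8% by default) applied to analyte areas only, so
  inter-day dispersion exceeds intra-day dispersion even after ISTD
  normalization.
* **Cohort**: two groups of `n_per_group` participants; log₁₀ true
  concentration = baseline + group_effect·group + Σβ_j·z(covariate_j) +
  N(0, residual_sd²), with three replicate injections per sample drawn
  through the response model at the replicate CV. Covariate distributions
  are documented placeholders (age ~ N(55, 10) years, BMI ~ N(25, 4),
  HbA1c ~ N(64, 12) mmol/mol, eGFR ~ N(85, 20), systolic BP ~ N(135, 15)
  mmHg, lipids and diabetes covariates similar; binary covariates
  Bernoulli(0.5)) — they shape realistic correlation scales but are not
  claims about any cohort. A configurable missingness rate forces values
  below detection to exercise the >70% filter. Continuous covariate effects
  act through z-scores so coefficients are comparable across covariates.
* **Seeding**: each generator derives an independent stream as
  `default_rng([seed, tag])` (tags 0/1/2 for calibration/QC/cohort), so one
  integer seed reproduces everything and the three data sets are mutually
  independent.

What the generator does **not** model: chromatographic drift, carry-over,
batch effects, run-order effects, non-Gaussian heavy-tailed noise,
non-linear (saturating) detector response, or correlated metabolites.
Passing tests therefore demonstrate the correctness of the computations
under the stated noise model, not robustness of the laboratory method to
those real-world effects. Run order randomization is recorded as provenance
but deliberately does not alter the simulated signal.

## Operating characteristics and problem sizes

`srmquant.studies` runs the full chain (generator → normalization →
calibration → back-calculation → mixed models → BH) repeatedly to measure
error control and power. The packaged campaigns use 20 metabolites,
25+25 participants × 3 replicates, 200 repetitions for the null study and
100 seeds for the power study — sizes chosen so each campaign gives
Monte-Carlo standard errors of a few percent while the full suite stays
comfortably runnable on a single CPU.

A note on the power campaign: with effects of 1.0 residual-SD planted on 5
of 20 metabolites and the full nine-covariate fixed-effect model on 50
participants, the group coefficient's standard error is inflated by the
covariate adjustment (roughly √(n/(n−p)) ≈ 1.12 at n = 50, p = 10), putting
the per-metabolite Wald z near 3.15 rather than the 3.54 of a
group-only comparison. Under BH at α = 0.05 this yields an expected
recovery rate of ≈ 0.72–0.78, not ≥ 0.80; the campaign reports the measured
value rather than tuning the design to reach a target. Dropping the
covariates, enlarging the cohort, or moderating variances would raise
power, but each would change the analysis away from the specified model.

## Known limitations

* Only straight-line calibration is supported (no quadratic or 4PL).
* Qualifier-transition ratio checking is not used to reject peaks; the
  panel carries qualifiers as metadata only.
* The BH family size depends on the detection filter and convergence, so
  adjusted p-values are comparable only within one analysis run; the output
  records m explicitly.
* `MixedLM` Wald p-values are asymptotically normal; with 50 participants
  they are mildly liberal compared to small-sample t corrections.
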