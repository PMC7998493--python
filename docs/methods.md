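# Methods

## The model

Each biomarker is analysed under a random-intercept linear mixed model on
its analysis scale (natural log or raw):

    y_ij = x_ij' β + b_i + e_ij,   b_i ~ N(0, σ²_b),  e_ij ~ N(0, σ²_w)

for subject i = 1..G at visit j.  The crude ("one-way") model has an
intercept only; the adjusted model adds the configured covariates as
fixed effects (cycle day, BMI, fasting hours, sleep hours, contraceptive
use, serum cholesterol, PAL, plus the biomarker-specific dietary intake —
purine for uric acid, vitamin C for vitamin C, tocopherol equivalents for
the tocopherols, retinol equivalents for retinol, β-carotene for the
carotenoids, energy otherwise).  Reliability is the intraclass
correlation ICC = σ²_b/(σ²_b + σ²_w).

**Estimation.** Restricted maximum likelihood via the profile over the
variance ratio λ = σ²_b/σ²_w.  For fixed λ the GLS fixed effects and the
REML residual variance are closed-form (block structure: per-subject
Sherman–Morrison), so the fit is a bounded 1-D search on log λ
(λ ∈ [e⁻³⁰, e³⁰], Brent) followed by a root-finding polish on the
analytic score, which locates the optimum to machine precision — the
objective itself is too flat near the optimum for a derivative-free
search to do better than ~1e-8 relative.  On balanced data the estimates
coincide with the one-way ANOVA moment estimators (σ̂²_w = MSW,
σ̂²_b = (MSB − MSW)/k), which the tests assert to 1e-8; on unbalanced
data the fit is cross-checked against an independent mixed-model
implementation (statsmodels MixedLM).  A between-variance estimate at the
zero boundary is truncated to 0 and flagged *singular*; the ICC of a
singular fit is reported as 0.000 and the index of individuality as
undefined ("/"), matching reliability-table conventions for analytes
whose between-subject variance vanishes (TEAC).

**Degenerate inputs.** All-constant data: singular components (0, 0),
ICC undefined (error on request).  Zero within-subject variance with
distinct subject means: σ²_w = 0, ICC = 1.  One visit for every subject:
unidentifiable, error.  Covariates constant over the used records carry
no information and are silently dropped from the design (so adjusting for
a constant reproduces the crude fit); genuinely collinear designs raise
an error naming the columns.

**Residuals.** Standardized *conditional* residuals
(y − x'β̂ − b̂_i)/σ̂_w with b̂_i the empirical BLUP
(shrinkage λn_i/(1+λn_i) of the subject's mean marginal residual).  The
paper-style sensitivity rule ">2.0" is applied to their absolute value.

**Bootstrap CI.** Subjects are resampled with replacement (all visits
travel with the subject), the model refitted, and the 2.5/97.5
percentiles taken, clipped to [0,1]; B = 2000 by default, deterministic
given the seed.  Percentile is the default construction
(normal-approximation available via config).  Measured coverage of the
percentile interval at ICC 0.7, n = 44, k = 3 is ≈ 91% at nominal 95% —
slight undercoverage is expected for a variance-ratio statistic at this
sample size and is the reason the acceptance band for coverage is 90–99%
rather than a point value.  Replicates that fail to fit are dropped; more
than 50% failures raise.

## Derived metrics

* CV conversion: on the log scale each component's SD converts through
  σ = √ln(CV²+1) ⇔ CV = √(exp(σ²)−1); on the raw scale CV = SD/mean.
  The two maps are exact inverses (asserted to 1e-12).
* II = CV_T/CV_G, undefined when CV_G = 0; thresholds 0.6/1.4.
* RCV: symmetric Z·√2·CV_T·100% for raw-scale biomarkers, asymmetric
  (exp(±Z√2σ)−1)·100% for log-scale ones, Z = 1.96 by default.  The
  upward RCV always exceeds the downward magnitude.
* n_β = [P/(1−P)]·(S²_w/S²_b) for attenuation 1−P ∈ {10%, 20%}; rounded
  down unless the fractional excess over the lower integer exceeds 0.20,
  floored at one measurement; undefined when S²_b = 0.  Equivalent
  parameterization by the ICC: S²_w/S²_b = (1−ICC)/ICC.
* ICC interpretation bands: ≥0.75 very good, 0.51–0.74 good, 0.40–0.50
  fair, <0.40 poor.  The quoted band edges leave (0.50, 0.51) unassigned;
  such values are classified *fair* with a warning.
* Sample size: the Fisher-transform (Walter–Eliasziw–Donner) form
  n = 1 + 2k(z_α + z_β)²/[(k−1)(ln C)²], C = (1+kθ₁)/(1+kθ₀),
  θ = ρ/(1−ρ), ceiled; dropout inflates by (1+rate) before the ceiling
  (0.30/0/3/5%/80% gives 35.46 → 36; with 20% dropout 43.2 → 44).  A
  Monte-Carlo F-test power check over 10,000 simulated cohorts confirms
  the n = 36 design reaches ≥ 80% power.

## Outlier screening

Cochran's C = max(s²_i)/Σs²_i on the within-subject variances, against
the F-quantile critical value C* = [1 + (n−1)/F]⁻¹ at quantile level α/n
(Bonferroni for the implicit maximum), df = modal visit count − 1.  The
closed form agrees with a 200,000-draw Monte-Carlo null within ±0.005 for
the design-relevant shapes.  The scan removes the most variable subject
and repeats until clean (single-pass switchable).  Reed's criterion flags
an extreme subject mean whose gap to its nearest neighbour exceeds a
third of the range, re-applied after each removal; with three values the
larger gap always exceeds range/3, so re-application stops once fewer
than four values remain.  Both screens run before modelling, iterating
jointly until neither flags.

Scale choice follows the published per-biomarker convention (natural log
for all biomarkers except bilirubin, eCAT, glutathione and TEAC),
overridable per config; without an override the package recommends the
log scale when Shapiro–Wilk rejects normality of the pooled
within-subject-centered values on the raw scale and the log scale fits at
least as well (p_log > p_raw).  Comparing p-values rather than re-testing
the log scale against α keeps the false-log rate near α on genuinely
normal data.  Bilirubin-style cases (non-normal yet conventionally
untransformed) are honoured by the override.

## Sensitivity analyses

*Residual mode*: after screening, all subjects with any |standardized
conditional residual| > 2.0 are dropped, the model refitted, repeated to
a fixed point (error if fewer than three subjects would remain); crude
and adjusted metrics are then recomputed.  *Subgroup mode*: subjects
flagged for contraceptive use, non-regular analgesics/antihistamines,
vaccination, abnormal cycle, health problems, or hs-CRP ≥ 95 nmol/L at
any visit are dropped; Cochran/Reed and residual inspection are repeated;
only crude metrics are reported (no adjusted ICC at the reduced n).

## Synthetic cohorts

The generator draws each biomarker from the random-intercept model on its
analysis scale with σ_b, σ_w derived from target CVs (log scale via
σ = √ln(CV²+1); raw scale σ = CV·μ), plus optional covariate effects with
slopes on the analysis scale — so the adjusted model is correctly
specified under simulation and recovery can be tested exactly.
Covariates decompose into subject-level and visit-level normal parts (or
subject-level Bernoulli flags).  Each biomarker and covariate uses an
independent seed substream keyed by its name, so adding a column never
changes the others.  Raw-scale draws are censored at a μ/1000
detection-limit floor, as an assay would censor at its LOQ (relevant only
for bilirubin-like CVs, ≈1% of draws).  Aberrant subjects are injected
separately: variance inflation multiplies a subject's within-subject
deviations, mean shift adds a multiple of σ_b.

The default spec mirrors the published study: 44 subjects × 3 visits and
the 17 biomarkers at their published mean and CV magnitudes.  What it
deliberately does *not* model: menstrual-cycle periodicity, assay drift,
cross-biomarker correlation (biomarkers are generated independently, so
the baseline Spearman matrix centers on zero), seasonal trends, and
real covariate–biomarker confounding unless effects are specified.
Passing recovery tests therefore demonstrates the estimators are correct
under the stated model, not that the model captures every feature of real
cohort data.

## Problem sizes used in validation

Parameter recovery: 500 cohorts (44×3) per true ICC in
{0.3, 0.5, 0.7, 0.875}, |mean bias| < 0.05.  Bootstrap coverage: 500
outer replicates at B = 200 (coverage 90–99% at nominal 95%; 500 outer
replicates keep the Monte-Carlo error of the coverage estimate near one
percentage point).  Cochran critical values: 200,000-draw null per shape.
Friedman: 1000 null cohorts (rejection ≈ 5%) and 200 shifted cohorts
(+1.5 σ_w at visit 3; detection with a distinct letter ≥ 90%).  The
analysis drivers use B = 300 for their demo reports; the library default
is B = 2000.

## Known limitations

* The adjusted-model bootstrap resamples subjects and refits the full
  covariate model; with many covariates and 44 subjects singular
  replicates are common for low-ICC biomarkers (they are dropped, and the
  failure rate is capped at 50%).
* Residual-mode exclusions are driven by the crude model's residuals;
  model-wise exclusion per adjusted model is available by calling
  `iterative_residual_exclusion` with covariates explicitly.
* The Goldberg screen's RMR equation coefficients are a documented,
  overridable configuration default (the cited adult equation); the
  screen's CVs default to the conventional 23/8.5/15%.
* No crossed or nested random effects, no Kenward–Roger small-sample
  corrections, no Bayesian alternatives.
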