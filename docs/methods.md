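# Methods

This package implements the analytic chain linking biomarker-based
biological-age acceleration and polygenic risk to incident abdominal
aortic aneurysm (AAA), together with a synthetic cohort generator that
provides known ground truth for every estimator in the chain.

## Biological-age models

**Klemera-Doubal biological age (KDM).** Within each sex, each of nine
biomarkers (FEV1, systolic blood pressure, albumin, alkaline phosphatase,
blood urea nitrogen, creatinine, C-reactive protein, glycated
haemoglobin, total cholesterol) is regressed on chronological age (CA) by
OLS, giving an intercept q_i, slope k_i and residual RMSE s_i. Biological
age is the precision-weighted mean of the per-biomarker implicit age
estimates and CA itself:

    BA = [ Σ_i (x_i − q_i) k_i / s_i² + CA / s_BA² ]
         / [ Σ_i (k_i / s_i)² + 1 / s_BA² ]

with s_BA² the variance of the fitted values from a multiple OLS of CA on
all nine biomarkers (the CA variance explained by the set). Two modelling
choices deserve note. First, the regression direction is
biomarker-on-age: this is the direction the weighted-mean structure
(x_i − q_i)·k_i/s_i² requires, and the canonical Klemera-Doubal
formulation. Second, s_BA is taken directly as the explained-CA variance;
the original Klemera-Doubal small-sample correction term is not applied
(a config flag is reserved for it). Training uses the post-exclusion
analysis cohort itself — a cross-sectional calibration, so KDM age is
centred on CA by construction in the training sample.

**Phenotypic age.** A fixed-coefficient linear predictor xb over nine
blood biomarkers plus CA (coefficients −19.907, −0.0336·albumin, …,
0.0804·CA; C-reactive protein enters as its natural log, floored at
0.01 mg/dL) is mapped through a Gompertz mortality model,

    mortality risk = 1 − exp(−1.51714 · exp(xb) / 0.0076927)
    PhenoAge = 141.50 + ln(−0.00553 · ln(1 − mortality risk)) / 0.09165.

The coefficients are immutable defaults in the published units (albumin
g/L, creatinine µmol/L, glucose mmol/L, CRP mg/dL, lymphocyte %, MCV fL,
RDW %, ALP U/L, WBC 10⁹/L); a different unit system must be converted
before calling. The implementation is validated against a frozen 50-digit
arbitrary-precision evaluation of the closed form (agreement to 1e-9).

**Age acceleration.** The residual of biological age regressed on CA over
the analysis sample, fitted sex-pooled (a config switch enables
stratified residualisation). Residual > 0 classifies a participant as
experiencing accelerated ageing; residuals within 1e-10 of zero (relative
to the bioage scale) are snapped to zero first, so inputs exactly on the
regression line classify as non-accelerated rather than inheriting the
sign of floating-point dust.

## Data preparation

Biomarkers are winsorized at the 1st/99th percentiles before any score is
computed, pooled across sexes by default (switchable). Percentiles use
linear interpolation between order statistics (numpy's default, "type
7"), declared in `WinsorizationSpec` so tests can pin the convention.
Winsorization is fit-and-apply on the baseline sample; the `Winsorizer`
object stores the cut points, and re-applying those stored cut points is
exactly idempotent. Re-*fitting* on already-winsorized data moves tail
values by at most the interpolation gap between adjacent order
statistics, which is why the projection-reuses-cut-points design was
chosen.

Continuous covariate gaps are imputed with the sex-stratified mean;
categorical gaps become an explicit "unknown" level. Biomarker gaps are
never imputed: participants missing any score biomarker are excluded, in
the fixed sequential order biomarkers → genetics → baseline vascular
disease, so each participant is counted under the first rule they fail
(flowchart-style accounting).

## Polygenic risk score

Weighted PRS = Σ_i β_i·dosage_i · N / Σ_i β_i over N = 31 risk variants,
with β the per-allele log odds ratios. The normalisation makes the score
invariant to rescaling all weights and reduces it to the allele count
when weights are equal — both enforced as property tests. Sporadic
missing dosages are imputed with twice the cohort effect-allele
frequency. Tertile cut points (sample 1/3 and 2/3 quantiles) define
low/intermediate/high genetic risk; a score exactly at a cut point goes
to the lower group. A minimal VCF importer reads the DS dosage field when
present, otherwise counts effect alleles from GT, flipping when the
effect allele is the reference allele.

## Survival machinery

Cox models use lifelines with Efron tie handling and Wald confidence
intervals on the log-HR scale (the conventions behind "HR (95% CI)"
reporting; the tie method is an assumption, stated here because large
administrative cohorts rarely report it). Categorical covariates expand
to treatment-coded dummies against a declared (or modal) reference. When
near-collinear covariates with few events leave the partial likelihood
flat, the fit retries once with a weak ridge (penalizer 1/n) and warns.

Proportional hazards are checked with the scaled-Schoenfeld-residual test
(rank-transformed time); the global statistic sums the per-term
chi-squares with matching degrees of freedom.

The quartile trend test replaces the exposure by its within-sample
quartile index (1–4) entered as a single continuous covariate; the Wald p
on that coefficient is the trend p.

Dose-response curves use Harrell's restricted cubic spline with three
knots at the exposure's 25th/50th/75th centiles — with three knots this
is the linear term plus one restricted truncated-power term, normalised
by (t₃ − t₁)². The curve is exp(f(x) − f(median)), so HR = 1 at the
median by construction; bands come from the delta method on the spline
coefficient covariance. Non-linearity is the Wald test on the restricted
term; the overall test is the joint Wald test on both terms.

Fine-Gray subdistribution fits are censoring-weighted Cox models on a
crprep-style expanded dataset: participants who die remain in later risk
sets with inverse-probability-of-censoring weights G(t)/G(T_death) from
the Kaplan-Meier estimate of the censoring distribution, their extended
follow-up split at its jump times. With zero competing deaths the
expansion is the identity and the fit coincides with the cause-specific
Cox model (verified to 1e-6, and cross-checked against the cmprsk R
package's crr estimator on a small cohort). Standard errors are
model-based, treating the weights as known — mildly conservative relative
to the sandwich form.

The landmark filter removes participants whose follow-up ended at or
before the landmark (default 2 years) and shifts remaining times down, to
blunt reverse causation. Subgroup analyses use a generic stratified-fit
utility plus a likelihood-ratio heterogeneity p on exposure-by-stratum
product terms, rather than bespoke code per subgroup.

## Interaction

Additive interaction uses the four-level cross-classified Cox model
(reference: non-accelerated, low genetic risk): RERI = HR11 − HR10 − HR01
+ 1 and AP = RERI/HR11, with percentile confidence intervals over 1000
individual-level bootstrap resamples (unstratified, participants with
replacement; bias correction is not applied). The cross-classified
parameterisation is algebraically identical to main-effects-plus-product
but matches joint-HR reporting and simplifies the bootstrap.
Multiplicative interaction is the likelihood ratio between Cox models
with and without the product terms.

Bootstrap refits use an internal vectorised Newton solver for the Efron
partial likelihood (`_coxcore`), cross-checked against lifelines to
≤1e-5 in the test suite; a full-featured fitter at every resample would
dominate the runtime of any bootstrap-heavy analysis.

## Mediation

The counterfactual decomposition works on the event-probability scale at
a fixed horizon (default: mean follow-up): a Gaussian OLS mediator model
(acceleration ~ pack-years + covariates) and a Cox outcome model with
Breslow baseline hazard. Potential mediator values under exposure x and
x+1 are simulated with common residual draws and pushed through the
outcome model:

    IE = E[P(x+1, M(x+1)) − P(x+1, M(x))],
    DE = E[P(x+1, M(x)) − P(x, M(x))],
    proportion mediated = IE / (IE + DE).

The probability scale (rather than log-hazard) was chosen because
reported indirect/direct effects of order 1e-5 per pack-year only make
sense as risk differences; the identity IE/(IE+DE) is the reproducible
quantity. The estimator assumes a rare outcome (warns above 5% event
fraction), no exposure-mediator interaction, and no unmeasured
mediator-outcome confounding. The percentile bootstrap over participants
gives the indirect-effect p.

## Synthetic cohort generator

The generator emulates a middle-aged population cohort: ages uniform on
40–70 (mean ≈ 55, close to the target population's 56.4 ± 8.1), 54.1%
female, pack-years zero-inflated gamma with 55.6% never-smokers (matching
44.4% ever-smokers), 14 biomarkers linear-Gaussian in age with sex
offsets and smoking displacement (parameters chosen for plausibility in
conventional clinical units; no real cohort's biomarker distributions
are targeted, so fidelity is not claimed), 31 SNP dosages
Binomial(2, f) with fixed frequencies and weights, genetic PCs and
genotyping batch as pure noise covariates, and competing latent
exponential AAA/death times with administrative censoring at 13.7 years
(first event wins). The default baseline AAA rate (1.558e-4/y) is
calibrated by deterministic root-finding so the default cohort accrues
≈0.54% incidence — the 1886-events-in-350,483 anchor; death ≈0.5%/y
flat.

"True acceleration" is defined as each participant's KDM-biomarker
deviation from its age+sex expectation projected through the KDM
precision weights k_i/s_i² — exactly the quantity the KDM acceleration
estimator measures up to a known shrinkage factor, which makes the
smoking→acceleration→AAA mediation path explicit and recoverable: the
true acceleration-on-pack-years slope is available in closed form
(`true_mediation_slope`). The simulated smoking-status indicator is
identically 1{pack_years > 0} (the zero-inflation component), so the
pipeline's default adjustment set carries pack-years only; both can be
used on data where they are distinct.

Because the generating hazard acts through the KDM-projected
acceleration, phenotypic-age acceleration — a different linear
combination of the biomarker noise, overlapping only through the four
shared markers — shows attenuated associations in simulated cohorts.
Recovery tests therefore target the KDM pathway; the phenotypic-age
estimators are validated against closed-form identities instead.

What the generator does **not** emulate: linkage disequilibrium between
variants, realistic UK population demographics, longitudinal biomarker
trajectories, informative censoring, and outcome misclassification.
Passing recovery tests therefore demonstrate estimator correctness under
the stated generating model, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulation-based checks use the following sizes, chosen so each check's
statistical requirement is met: Cox recovery 100 replicates of n =
20,000 (mean bias tolerance 0.03 ≈ 4.7 Monte-Carlo SEs); type-I error
suites 200 replicates of n = 3,000 with ~8% events (size properties need
events, not large n; counts compared against the exact central 99%
binomial band); RERI null at n = 20,000 and additive-excess power at n =
50,000, each with 1000-resample bootstraps; mediation recovery at n =
50,000 with the generator calibrated to a ~10% true proportion via path
coefficients (direct log-HR 0.018 per pack-year, mediator log-HR 0.04
per year, acceleration slope 0.05 y per pack-year), the truth computed
by Monte-Carlo integration of the counterfactual contrasts under the
generating parameters. Method-validation scenarios use ~4–8% event
rates; the cohort-emulation default keeps the calibrated 0.54%.

Numerical conventions: quantiles are numpy type 7 throughout; values
exactly at a quartile/tertile cut point go to the lower group; Newton
iterations stop at |Δ log-likelihood| < 1e-9 with step-halving; the
degenerate inputs (no events, constant covariates, zero CA variance,
coincident knots, all-missing dosage columns, empty interaction
cross-cells) raise typed errors naming the offending column or cell.

## Known limitations

- The mediation estimand is a per-unit risk difference at one horizon;
  it is not a full natural-effects decomposition (no exposure-mediator
  interaction term, single mediator).
- Fine-Gray standard errors ignore the estimation of the censoring
  weights.
- The KDM s_BA estimator omits the original small-sample correction.
- The generator's biomarker parameters are plausible, not fitted to any
  real cohort; absolute hazard ratios produced by the pipeline on
  simulated data are not comparable to published cohort estimates.
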