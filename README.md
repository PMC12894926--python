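# ageaccel

Biological-age acceleration, polygenic risk, and incident abdominal
aortic aneurysm (AAA): a tested analysis pipeline with a synthetic cohort
generator providing known ground truth.

## The problem

AAA is a degenerative vascular disease of ageing, yet calendar age is a
crude proxy for the physiological state that actually drives risk. Two
blood-chemistry "clocks" quantify that state as an age-equivalent score:

- **Klemera-Doubal biological age (KDM)** — per-sex OLS of each of nine
  biomarkers x_i on chronological age (CA) gives intercept q_i, slope
  k_i and residual RMSE s_i; biological age is the precision-weighted
  mean

  `BA = [Σ_i (x_i − q_i) k_i / s_i² + CA / s_BA²] / [Σ_i (k_i/s_i)² + 1/s_BA²]`,

  where s_BA² is the CA variance explained by the biomarker set.
- **Phenotypic age (PhenoAge)** — a fixed linear predictor xb over nine
  blood biomarkers plus CA, mapped through a Gompertz mortality model:
  `mortality risk = 1 − exp(−1.51714·e^xb / 0.0076927)`,
  `PhenoAge = 141.50 + ln(−0.00553·ln(1 − risk)) / 0.09165`.

**Age acceleration** is the residual of biological age on CA; a positive
residual flags accelerated ageing. Genetic predisposition enters as a
weighted polygenic risk score over 31 risk variants,
`PRS = Σ_i β_i·dosage_i · N / Σ_i β_i`, grouped by tertiles.

The pipeline links these to incident AAA with the epidemiologist's full
toolkit: adjusted Cox proportional-hazards models (binary accelerated
flag, per-SD continuous, quartiles with a 1-4 trend test), Schoenfeld
proportional-hazards diagnostics, restricted-cubic-spline dose-response
(3 knots, HR = 1 at the median), additive interaction
(RERI = HR11 − HR10 − HR01 + 1, AP = RERI/HR11, bootstrap CIs) and
multiplicative interaction (likelihood ratio), counterfactual mediation
of smoking through age acceleration (IE/DE on the risk scale, proportion
mediated = IE/(IE+DE)), and sensitivity analyses (2-year landmark,
complete-case, non-poor-health, Fine-Gray competing-risk).

Cohort-scale biobank data are access-restricted, so the package ships a
first-class synthetic cohort generator (`ageaccel.simulate`) whose
defaults emulate the study conditions — ages 40-70, 54% female, 44%
ever-smokers, ~0.54% AAA incidence over 13.7 years with death as a
competing event — and expose every generating parameter so the chain's
estimators are tested by parameter recovery. See `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the chain on a simulated
20,000-participant cohort and write tidy tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # cohort + truth + exclusions
python analysis/02_bioage_scores.py     # KDM, PhenoAge, acceleration
python analysis/03_polygenic_risk.py    # weighted PRS, tertiles
python analysis/04_survival_models.py   # Cox / trend / spline / PH
python analysis/05_interaction.py       # joint groups, RERI/AP, LRT
python analysis/06_mediation.py         # smoking -> acceleration -> AAA
python analysis/07_sensitivity.py       # landmark, complete-case, Fine-Gray
```

Output of the first two steps:

```
simulated 20000 participants (seed 1)
  AAA events: 133 (0.66%), deaths: 1384
  excluded by missing_biomarker: 1070 (remaining 18930)
  excluded by missing_genetics: 126 (remaining 18804)
  excluded by baseline_vascular: 99 (remaining 18705)
scored 18705 participants
  kdm       acceleration mean -0.000 (SD 2.604) years; 49.4% accelerated
  phenoage  acceleration mean +0.000 (SD 4.386) years; 49.9% accelerated
```

The event fraction sits near the calibrated 0.54% target, and both
acceleration distributions are mean-zero by construction (they are OLS
residuals), with roughly half the cohort flagged accelerated. The main
model step then reports, e.g.:

```
kdm: accelerated HR 2.43 (1.56-3.78), per-SD HR 1.73, trend p 5.79e-07,
     RCS non-linearity p 0.36, PH global p 0.25
```

— the generating hazard rises log-linearly with true acceleration, so
the spline correctly finds no non-linearity, the quartile trend is
strongly positive, and proportional hazards hold. The mediation step
recovers the generator's smoking→acceleration→AAA path
(`kdm: proportion mediated 43.25%, bootstrap p 0.005` under the default
generator's strong smoking displacement), while the sensitivity step
shows the landmark, complete-case and Fine-Gray variants agreeing with
the main fit, as they should when censoring is administrative and
competing mortality is independent.

Everything the scripts do is a thin call into the library: the same
steps are available programmatically (`simulate_cohort`,
`fit_kdm_model`, `compute_phenoage`, `compute_weighted_prs`, `fit_cox`,
`rcs_dose_response`, `estimate_additive_interaction`, `run_mediation`,
`fit_fine_gray`, `run_pipeline`) and through a small CLI
(`ageaccel simulate|bioage|prs|run`).

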