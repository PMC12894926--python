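"""End-to-end pipeline: preparation -> scores -> PRS -> models -> interaction
-> mediation -> sensitivity variants.

``run_pipeline`` executes the full analytic chain on a cohort table
(simulated or loaded), logging participant and event counts per stage, and
returns a result bundle of tidy tables and scalars.  Deterministic given
the configured seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ageaccel import io as aio
from ageaccel.bioage import fit_kdm_model, save_kdm_models, score_cohort
from ageaccel.interaction import (
    build_joint_groups,
    estimate_additive_interaction,
    joint_group_hrs,
    test_multiplicative_interaction,
)
from ageaccel.mediation import run_mediation
from ageaccel.prep import apply_exclusions, impute_covariates, winsorize_biomarkers
from ageaccel.prs import assign_genetic_risk_groups, compute_weighted_prs, default_weights, impute_missing_dosage
from ageaccel.survival import (
    fit_cox,
    fit_fine_gray,
    landmark_filter,
    quartile_dummies,
    quartile_trend_test,
    rcs_dose_response,
    test_proportional_hazards,
)

logger = logging.getLogger("ageaccel.pipeline")

# the simulated smoking indicator is exactly 1{pack_years > 0}, so the
# default adjustment set carries pack-years only; pass a custom covariate
# list to adjust for both on data where they are distinct
DEFAULT_COVARIATES = [
    "chronological_age", "sex", "bmi", "townsend", "education",
    "pack_years", "self_reported_health",
]
GENETIC_COVARIATES = ["genotyping_batch"] + [f"pc{i}" for i in range(1, 11)]


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    weights_path: str | None = None
    output_dir: str = "results"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    genetic_covariates: list[str] = field(default_factory=lambda: list(GENETIC_COVARIATES))
    winsorize_lower: float = 0.01
    winsorize_upper: float = 0.99
    seed: int = 0
    n_boot_interaction: int = 1000
    n_boot_mediation: int = 200
    n_sims_mediation: int = 1000
    landmark_years: float = 2.0
    run_landmark: bool = True
    run_complete_case: bool = True
    run_exclude_poor_health: bool = True
    run_fine_gray: bool = True
    snp_betas: list[float] | None = None  # used when no weights file given

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.cohort_path, self.weights_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def _stage(name: str, cohort: pd.DataFrame, event_col: str = "aaa_event") -> None:
    logger.info(
        "stage %-24s n=%d events=%d", name, len(cohort), int(cohort[event_col].sum())
    )


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame | None = None,
    snp_betas: np.ndarray | None = None,
) -> dict:
    """Run the full chain and return a result bundle (dict of tables and
    scalars).  Also writes tables under ``config.output_dir``."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if config.cohort_path is None:
            raise ValueError("no cohort given: set cohort_path or pass a table")
        cohort = aio.read_cohort(config.cohort_path)
    _stage("input", cohort)

    # ---- preparation ---------------------------------------------------
    cohort, exclusion_report = apply_exclusions(cohort)
    _stage("exclusions", cohort)
    cohort = impute_covariates(cohort)
    from ageaccel.prep import WinsorizationSpec
    spec = WinsorizationSpec(config.winsorize_lower, config.winsorize_upper)
    cohort = winsorize_biomarkers(cohort, spec=spec)
    _stage("prepared", cohort)

    # ---- biological-age scores ----------------------------------------
    kdm_models = {
        sex: fit_kdm_model(cohort, sex) for sex in ("male", "female")
    }
    scored = score_cohort(cohort, kdm_models)
    _stage("scored", scored)

    # ---- polygenic risk score ------------------------------------------
    snp_cols = sorted(c for c in scored.columns if c.startswith("snp_"))
    if config.weights_path:
        from ageaccel.prs import PRSWeights
        weights = PRSWeights.from_tsv(config.weights_path)
    else:
        betas = snp_betas if snp_betas is not None else config.snp_betas
        if betas is None:
            raise ValueError("no PRS weights: set weights_path or pass snp_betas")
        weights = default_weights(np.asarray(betas, dtype=float))
    dosages = impute_missing_dosage(scored[snp_cols])
    scored["prs"] = compute_weighted_prs(weights, dosages)
    risk, cuts = assign_genetic_risk_groups(scored["prs"].to_numpy())
    scored["genetic_risk"] = risk.astype(str)
    scored["high_genetic_risk"] = (scored["genetic_risk"] == "high").astype(int)
    _stage("prs", scored)

    covs = config.covariates
    results: dict = {
        "exclusion_report": exclusion_report,
        "prs_tertile_cuts": cuts,
        "n": len(scored),
        "n_events": int(scored["aaa_event"].sum()),
        "aaa_event_fraction": float(scored["aaa_event"].mean()),
    }

    # ---- main survival models ------------------------------------------
    main_rows = []
    for score in ("kdm", "phenoage"):
        accel_col = f"{score}_accel"
        flag_col = f"{score}_accelerated"
        adj = covs
        fit_bin = fit_cox(scored, flag_col, adj)
        fit_sd = fit_cox(scored, accel_col, adj, per_sd=True)
        trend = quartile_trend_test(scored, accel_col, adj)
        qd = quartile_dummies(scored[accel_col].to_numpy(), prefix=f"{score}_q")
        work = pd.concat([scored, qd], axis=1)
        fit_q = fit_cox(work, list(qd.columns), adj)
        ph = test_proportional_hazards(fit_bin)
        rcs = rcs_dose_response(scored, accel_col, adj)
        rcs.grid.to_csv(outdir / f"dose_response_{score}.tsv", sep="\t", index=False)
        for _, row in fit_q.summary.iterrows():
            if row["term"].startswith(f"{score}_q"):
                main_rows.append({"score": score, "term": row["term"],
                                  "hr": row["hr"], "ci_low": row["ci_low"],
                                  "ci_high": row["ci_high"], "p": row["p"]})
        main_rows.append({"score": score, "term": "per_sd",
                          "hr": fit_sd.hr(accel_col),
                          "ci_low": float(fit_sd.summary.set_index("term").loc[accel_col, "ci_low"]),
                          "ci_high": float(fit_sd.summary.set_index("term").loc[accel_col, "ci_high"]),
                          "p": float(fit_sd.summary.set_index("term").loc[accel_col, "p"])})
        main_rows.append({"score": score, "term": "accelerated",
                          "hr": fit_bin.hr(flag_col),
                          "ci_low": float(fit_bin.summary.set_index("term").loc[flag_col, "ci_low"]),
                          "ci_high": float(fit_bin.summary.set_index("term").loc[flag_col, "ci_high"]),
                          "p": float(fit_bin.summary.set_index("term").loc[flag_col, "p"])})
        results[f"{score}_accelerated_hr"] = fit_bin.hr(flag_col)
        results[f"{score}_per_sd_hr"] = fit_sd.hr(accel_col)
        results[f"{score}_trend_p"] = trend["p_trend"]
        results[f"{score}_rcs_p_nonlinear"] = rcs.p_nonlinear
        results[f"{score}_rcs_p_overall"] = rcs.p_overall
        results[f"{score}_ph_global_p"] = float(
            ph.loc[ph["term"] == "GLOBAL", "p"].iloc[0]
        )
    main_table = pd.DataFrame(main_rows)
    aio.write_tidy_tsv(main_table, outdir / "main_hazard_ratios.tsv")
    results["main_table"] = main_table
    _stage("survival", scored)

    # ---- joint groups, interaction ------------------------------------
    gcovs = [c for c in covs + config.genetic_covariates if c in scored.columns]
    inter_rows = []
    for score in ("kdm", "phenoage"):
        flag_col = f"{score}_accelerated"
        joint = build_joint_groups(
            scored[flag_col].to_numpy(dtype=bool), scored["genetic_risk"].to_numpy()
        )
        jfit = joint_group_hrs(scored, joint, gcovs)
        aio.write_tidy_tsv(jfit.summary, outdir / f"joint_groups_{score}.tsv")
        inter = estimate_additive_interaction(
            scored, flag_col, "high_genetic_risk", gcovs,
            n_boot=config.n_boot_interaction, seed=config.seed,
        )
        mult = test_multiplicative_interaction(scored, flag_col, "genetic_risk", gcovs)
        inter_rows.append({
            "score": score, "reri": inter.reri, "reri_lo": inter.reri_ci[0],
            "reri_hi": inter.reri_ci[1], "ap": inter.ap,
            "ap_lo": inter.ap_ci[0], "ap_hi": inter.ap_ci[1],
            "p_multiplicative": mult["p"],
        })
        results[f"{score}_interaction"] = inter
        results[f"{score}_p_multiplicative"] = mult["p"]
    inter_table = pd.DataFrame(inter_rows)
    aio.write_tidy_tsv(inter_table, outdir / "interaction.tsv")
    results["interaction_table"] = inter_table
    _stage("interaction", scored)

    # ---- mediation ------------------------------------------------------
    med_covs = [c for c in covs if c not in ("pack_years", "smoking_status")]
    med_rows = []
    for score in ("kdm", "phenoage"):
        med = run_mediation(
            scored, exposure="pack_years", mediator=f"{score}_accel",
            covariates=med_covs, n_sims=config.n_sims_mediation,
            n_boot=config.n_boot_mediation, seed=config.seed,
        )
        med_rows.append({"score": score, "ie": med.ie, "de": med.de,
                         "proportion_mediated": med.proportion_mediated,
                         "p": med.p_ie})
        results[f"{score}_mediation"] = med
    med_table = pd.DataFrame(med_rows)
    aio.write_tidy_tsv(med_table, outdir / "mediation.tsv")
    results["mediation_table"] = med_table
    _stage("mediation", scored)

    # ---- sensitivity variants ------------------------------------------
    sens_rows = []
    variants: list[tuple[str, pd.DataFrame]] = []
    if config.run_landmark:
        variants.append(("landmark", landmark_filter(scored, config.landmark_years)))
    if config.run_exclude_poor_health:
        variants.append(
            ("non_poor_health", scored.loc[scored["self_reported_health"] != "poor"])
        )
    if config.run_complete_case:
        variants.append(("complete_case", scored.dropna(subset=covs)))
    for name, sub in variants:
        for score in ("kdm", "phenoage"):
            f = fit_cox(sub, f"{score}_accelerated", covs)
            sens_rows.append({"variant": name, "score": score,
                              "hr": f.hr(f"{score}_accelerated"), "n": f.n,
                              "events": f.n_events})
    if config.run_fine_gray:
        for score in ("kdm", "phenoage"):
            fg = fit_fine_gray(scored, f"{score}_accelerated", covs)
            sens_rows.append({"variant": "fine_gray", "score": score,
                              "hr": fg.hr(f"{score}_accelerated"), "n": fg.n,
                              "events": fg.n_events})
    sens_table = pd.DataFrame(sens_rows)
    aio.write_tidy_tsv(sens_table, outdir / "sensitivity.tsv")
    results["sensitivity_table"] = sens_table
    _stage("sensitivity", scored)

    # ---- outputs --------------------------------------------------------
    save_kdm_models(kdm_models, outdir / "kdm_models.json")
    score_table = scored[
        ["participant_id", "kdm_age", "phenoage", "kdm_accel", "phenoage_accel",
         "kdm_accelerated", "phenoage_accelerated", "prs", "genetic_risk"]
    ]
    aio.write_tidy_tsv(score_table, outdir / "participant_scores.tsv")
    aio.write_results_json(
        {k: v for k, v in results.items()
         if isinstance(v, (int, float, str, list, tuple))},
        outdir / "summary.json",
    )
    results["scored_cohort"] = scored
    results["kdm_models"] = kdm_models
    return results
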