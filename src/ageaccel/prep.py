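"""Biomarker winsorization, covariate imputation and cohort exclusion filters.

Preparation steps applied before any biological-age score is computed:
extreme biomarker values are clamped to the 1st/99th percentiles,
continuous covariate gaps are filled with the sex-stratified mean,
categorical gaps become an explicit ``"unknown"`` level, and participants
failing the inclusion rules (missing score biomarkers, missing genetics,
baseline vascular disease) are removed with sequential accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ageaccel.simulate import ALL_BIOMARKERS

#: exclusion rules in the fixed application order
EXCLUSION_RULES = ("missing_biomarker", "missing_genetics", "baseline_vascular")


@dataclass(frozen=True)
class WinsorizationSpec:
    lower_percentile: float = 0.01
    upper_percentile: float = 0.99
    percentile_rule: str = "linear"  # numpy interpolation method (type 7)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_percentile < self.upper_percentile <= 1.0:
            raise ValueError("need 0 <= lower < upper <= 1")


@dataclass
class Winsorizer:
    """Fit-and-apply winsorization with stored cut points.

    Cut points are learned on a baseline sample and can be re-applied to new
    data (projection), mirroring a cross-sectional calibrate-once workflow.
    """

    spec: WinsorizationSpec = field(default_factory=WinsorizationSpec)
    lower_: float | None = None
    upper_: float | None = None

    def fit(self, values: np.ndarray) -> "Winsorizer":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError("winsorization needs at least 2 finite values")
        self.lower_ = float(
            np.quantile(v, self.spec.lower_percentile, method=self.spec.percentile_rule)
        )
        self.upper_ = float(
            np.quantile(v, self.spec.upper_percentile, method=self.spec.percentile_rule)
        )
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.lower_ is None:
            raise ValueError("Winsorizer not fitted")
        v = np.asarray(values, dtype=float)
        return np.clip(v, self.lower_, self.upper_)


def winsorize_panel(
    values: np.ndarray, spec: WinsorizationSpec | None = None
) -> np.ndarray:
    """Clamp a biomarker vector to its own lower/upper percentiles.

    NaN entries pass through unchanged (they are handled by the exclusion
    step, never silently imputed here).
    """
    spec = spec or WinsorizationSpec()
    w = Winsorizer(spec).fit(values)
    v = np.asarray(values, dtype=float)
    out = v.copy()
    finite = np.isfinite(v)
    out[finite] = w.transform(v[finite])
    return out


def winsorize_biomarkers(
    cohort: pd.DataFrame,
    biomarkers: list[str] | None = None,
    spec: WinsorizationSpec | None = None,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Winsorize each biomarker column; pooled across sexes by default."""
    biomarkers = biomarkers or [b for b in ALL_BIOMARKERS if b in cohort.columns]
    out = cohort.copy()
    if by_sex:
        for _, idx in cohort.groupby("sex").groups.items():
            for b in biomarkers:
                out.loc[idx, b] = winsorize_panel(cohort.loc[idx, b].to_numpy(), spec)
    else:
        for b in biomarkers:
            out[b] = winsorize_panel(cohort[b].to_numpy(), spec)
    return out


def impute_covariates(
    cohort: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Fill covariate gaps: sex-stratified mean for continuous columns,
    an explicit ``"unknown"`` level for categorical columns.

    Biomarker columns are never imputed; participants missing a score
    biomarker are excluded upstream by :func:`apply_exclusions`.
    """
    if cohort["sex"].isna().any():
        raise ValueError("sex must be fully observed for stratified imputation")
    out = cohort.copy()
    if covariates is None:
        skip = set(ALL_BIOMARKERS) | {
            "participant_id", "sex", "time_years", "aaa_event", "death_event",
            "true_acceleration",
        }
        covariates = [c for c in cohort.columns if c not in skip and not c.startswith("snp_")]
    for col in covariates:
        if col not in out.columns:
            raise KeyError(f"unknown covariate: {col}")
        missing = out[col].isna()
        if not missing.any():
            continue
        if pd.api.types.is_numeric_dtype(out[col]):
            means = out.groupby("sex", observed=True)[col].transform("mean")
            if means[missing].isna().any():
                bad = out.loc[missing & means.isna(), "sex"].unique()
                raise ValueError(
                    f"stratum mean undefined for covariate '{col}' in sex stratum {list(bad)}"
                )
            out.loc[missing, col] = means[missing]
        else:
            out[col] = out[col].astype(object)
            out.loc[missing, col] = "unknown"
    return out


def apply_exclusions(
    cohort: pd.DataFrame,
    rules: tuple[str, ...] = EXCLUSION_RULES,
    biomarkers: list[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove participants failing the active inclusion rules.

    Rules are applied sequentially in the canonical order (score biomarkers,
    then genetics, then baseline vascular disease), so a participant failing
    several rules is counted only under the first — matching flowchart-style
    sequential accounting.

    Returns the filtered cohort and a report: one ``{"rule", "removed",
    "remaining"}`` record per active rule.
    """
    for r in rules:
        if r not in EXCLUSION_RULES:
            raise ValueError(f"unknown exclusion rule: {r!r}")
    biomarkers = biomarkers or [b for b in ALL_BIOMARKERS if b in cohort.columns]
    snp_cols = [c for c in cohort.columns if c.startswith("snp_")]
    out = cohort
    report: list[dict] = []
    for rule in EXCLUSION_RULES:  # canonical order regardless of `rules` order
        if rule not in rules:
            continue
        if rule == "missing_biomarker":
            fail = out[biomarkers].isna().any(axis=1)
        elif rule == "missing_genetics":
            fail = (
                out[snp_cols].isna().any(axis=1)
                if snp_cols
                else pd.Series(False, index=out.index)
            )
        else:  # baseline_vascular
            fail = (
                out["baseline_vascular_disease"].fillna(0).astype(int) == 1
                if "baseline_vascular_disease" in out.columns
                else pd.Series(False, index=out.index)
            )
        out = out.loc[~fail]
        report.append(
            {"rule": rule, "removed": int(fail.sum()), "remaining": int(len(out))}
        )
    return out.copy(), report
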