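"""Joint exposure-by-genetic-risk classification and interaction measures.

Additive interaction between a binary exposure (accelerated ageing) and a
binary high-genetic-risk flag is quantified on the hazard-ratio scale by
the relative excess risk due to interaction and the attributable
proportion,

    RERI = HR11 - HR10 - HR01 + 1,        AP = RERI / HR11,

with percentile confidence intervals over individual-level bootstrap
resamples (zero inside the interval = no additive interaction).
Multiplicative interaction is tested by the likelihood ratio between Cox
models with and without exposure-by-risk product terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ageaccel._coxcore import cox_newton
from ageaccel.survival import CoxFitResult, expand_covariates, fit_cox

JOINT_LEVELS = [
    "low|non_accelerated",
    "low|accelerated",
    "intermediate|non_accelerated",
    "intermediate|accelerated",
    "high|non_accelerated",
    "high|accelerated",
]


def build_joint_groups(
    accelerated: np.ndarray, risk_group: pd.Categorical | np.ndarray
) -> pd.Categorical:
    """Six-level accelerated-ageing x genetic-risk factor.

    Reference level is (low genetic risk, non-accelerated); levels are
    ordered low -> intermediate -> high, non-accelerated before accelerated
    within each risk group, matching joint-association HR tables.
    """
    acc = np.asarray(accelerated).astype(bool)
    risk = np.asarray(risk_group).astype(str)
    labels = np.char.add(
        risk, np.where(acc, "|accelerated", "|non_accelerated")
    )
    return pd.Categorical(labels, categories=JOINT_LEVELS, ordered=True)


def build_joint_groups_quartile(
    quartile: np.ndarray, risk_group: pd.Categorical | np.ndarray
) -> pd.Categorical:
    """Twelve-level exposure-quartile x genetic-risk factor; reference is
    (Q1, low genetic risk)."""
    q = np.asarray(quartile).astype(int)
    risk = np.asarray(risk_group).astype(str)
    labels = np.array([f"{r}|Q{k}" for r, k in zip(risk, q)])
    cats = [f"{r}|Q{k}" for r in ("low", "intermediate", "high") for k in (1, 2, 3, 4)]
    return pd.Categorical(labels, categories=cats, ordered=True)


def reri_ap_from_hrs(hr10: float, hr01: float, hr11: float) -> dict:
    """Formula layer: additive-interaction measures from component HRs.

    ``hr10``: exposure only, ``hr01``: high risk only, ``hr11``: both,
    each relative to the doubly-unexposed reference.
    """
    reri = hr11 - hr10 - hr01 + 1.0
    return {"reri": reri, "ap": reri / hr11,
            "hr10": hr10, "hr01": hr01, "hr11": hr11}


@dataclass
class InteractionResult:
    reri: float
    ap: float
    reri_ci: tuple[float, float]
    ap_ci: tuple[float, float]
    hr10: float
    hr01: float
    hr11: float
    n_boot: int
    additive_interaction_significant: bool


def _cross_class_design(
    cohort: pd.DataFrame, exposure: str, highrisk: str,
    covariates: list[str] | None,
) -> tuple[np.ndarray, list[str]]:
    e = cohort[exposure].to_numpy(dtype=float)
    g = cohort[highrisk].to_numpy(dtype=float)
    if not set(np.unique(e)) <= {0.0, 1.0} or not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValueError("exposure and high-risk flags must be binary 0/1")
    g10 = e * (1 - g)
    g01 = (1 - e) * g
    g11 = e * g
    cols = [g10, g01, g11]
    names = ["g10", "g01", "g11"]
    if covariates:
        extra = expand_covariates(cohort, covariates)
        cols += [extra[c].to_numpy(dtype=float) for c in extra.columns]
        names += list(extra.columns)
    return np.column_stack(cols), names


def estimate_additive_interaction(
    cohort: pd.DataFrame,
    exposure: str,
    highrisk: str,
    covariates: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> InteractionResult:
    """RERI and AP from the four-level cross-classified Cox model, with
    percentile bootstrap confidence intervals over participant resamples."""
    ev = cohort[event_col].to_numpy(dtype=int)
    e = cohort[exposure].to_numpy(dtype=float)
    g = cohort[highrisk].to_numpy(dtype=float)
    if not set(np.unique(e)) <= {0.0, 1.0} or not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValueError("exposure and high-risk flags must be binary 0/1")
    for ee in (0, 1):
        for gg in (0, 1):
            cell = (e == ee) & (g == gg)
            if ev[cell].sum() < 1:
                raise ValueError(
                    f"no events in cross-class (exposure={ee}, highrisk={gg})"
                )
    x, _ = _cross_class_design(cohort, exposure, highrisk, covariates)
    t = cohort[duration_col].to_numpy(dtype=float)

    fit = cox_newton(x, t, ev)
    hr10, hr01, hr11 = np.exp(fit.beta[:3])
    point = reri_ap_from_hrs(hr10, hr01, hr11)

    rng = np.random.default_rng(seed)
    n = len(cohort)
    reri_b = np.empty(n_boot)
    ap_b = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            fb = cox_newton(x[idx], t[idx], ev[idx])
            h10, h01, h11 = np.exp(fb.beta[:3])
            reri_b[b] = h11 - h10 - h01 + 1.0
            ap_b[b] = reri_b[b] / h11
        except (ValueError, np.linalg.LinAlgError):
            reri_b[b] = np.nan
            ap_b[b] = np.nan
    reri_ci = tuple(np.nanpercentile(reri_b, [2.5, 97.5]))
    ap_ci = tuple(np.nanpercentile(ap_b, [2.5, 97.5]))
    signif = not (reri_ci[0] <= 0.0 <= reri_ci[1])
    return InteractionResult(
        reri=point["reri"], ap=point["ap"],
        reri_ci=(float(reri_ci[0]), float(reri_ci[1])),
        ap_ci=(float(ap_ci[0]), float(ap_ci[1])),
        hr10=float(hr10), hr01=float(hr01), hr11=float(hr11),
        n_boot=n_boot, additive_interaction_significant=bool(signif),
    )


def test_multiplicative_interaction(
    cohort: pd.DataFrame,
    exposure: str,
    risk: str,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> dict:
    """Likelihood-ratio test of exposure-by-risk product terms in the Cox
    model; ``risk`` may be binary or a multi-level categorical."""
    work = cohort.copy()
    risk_col = work[risk]
    if pd.api.types.is_numeric_dtype(risk_col):
        risk_dummies = pd.DataFrame({f"{risk}": risk_col.astype(float)})
    else:
        risk_dummies = expand_covariates(work, [risk])
    base = [exposure] + list(risk_dummies.columns)
    for c in risk_dummies.columns:
        work[c] = risk_dummies[c]
    prods = []
    for c in risk_dummies.columns:
        nm = f"{exposure}:{c}"
        work[nm] = work[exposure].astype(float) * risk_dummies[c]
        prods.append(nm)
    null_fit = fit_cox(work, base, covariates,
                       duration_col=duration_col, event_col=event_col)
    full_fit = fit_cox(work, base + prods, covariates,
                       duration_col=duration_col, event_col=event_col)
    lr = 2.0 * (full_fit.loglik - null_fit.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), len(prods)))
    return {"lrt": float(max(lr, 0.0)), "df": len(prods), "p": p,
            "null_fit": null_fit, "full_fit": full_fit}


def joint_group_hrs(
    cohort: pd.DataFrame,
    joint: pd.Categorical,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> CoxFitResult:
    """HR table for a joint factor against its first (reference) level."""
    work = cohort.copy()
    present = set(np.asarray(joint.astype(str)))
    cats = [lv for lv in joint.categories if lv in present]
    dummies = []
    for lv in cats[1:]:
        nm = f"joint[{lv}]"
        work[nm] = (np.asarray(joint.astype(str)) == lv).astype(float)
        dummies.append(nm)
    return fit_cox(work, dummies, covariates,
                   duration_col=duration_col, event_col=event_col)
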