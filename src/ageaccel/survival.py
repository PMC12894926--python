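"""Cox proportional-hazards machinery for incident-event analysis.

Adjusted hazard ratios (lifelines, Efron ties, Wald confidence intervals on
the log-HR scale), Schoenfeld-residual proportional-hazards diagnostics,
quartile trend tests (quartile index 1-4 entered as a single continuous
covariate), restricted-cubic-spline dose-response curves (Harrell basis,
three knots at the 25th/50th/75th centiles, hazard ratio referenced to the
exposure median), Fine-Gray subdistribution-hazard fits treating death as a
competing event (censoring-weighted partial likelihood), and landmark
sensitivity filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats


@dataclass
class CoxFitResult:
    """Tidy per-term Cox estimates plus fit metadata."""

    summary: pd.DataFrame  # term, loghr, se, hr, ci_low, ci_high, p
    loglik: float
    n: int
    n_events: int
    model: object = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)

    def loghr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "loghr"])

    def hr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "hr"])


def expand_covariates(
    cohort: pd.DataFrame,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Expand categorical covariates to treatment-coded dummies.

    The reference level is the declared one where given, otherwise the most
    frequent level.
    """
    reference_levels = reference_levels or {}
    blocks = []
    for cov in covariates:
        col = cohort[cov]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.astype(float).rename(cov))
        else:
            ref = reference_levels.get(cov, col.mode().iloc[0])
            levels = [lv for lv in pd.unique(col.dropna()) if lv != ref]
            for lv in sorted(map(str, levels)):
                blocks.append((col.astype(str) == lv).astype(float).rename(f"{cov}[{lv}]"))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=cohort.index)


def _wald_summary(params: pd.Series, se: pd.Series) -> pd.DataFrame:
    z = params / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": params.index,
            "loghr": params.to_numpy(),
            "se": se.to_numpy(),
            "hr": np.exp(params.to_numpy()),
            "ci_low": np.exp(params.to_numpy() - 1.959963984540054 * se.to_numpy()),
            "ci_high": np.exp(params.to_numpy() + 1.959963984540054 * se.to_numpy()),
            "p": p,
        }
    ).reset_index(drop=True)


def fit_cox(
    cohort: pd.DataFrame,
    exposure: str | list[str],
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
    per_sd: bool = False,
    reference_levels: dict[str, str] | None = None,
) -> CoxFitResult:
    """Adjusted Cox proportional-hazards fit (Efron tie handling).

    ``exposure`` may be a single column (continuous or binary; with
    ``per_sd=True`` a continuous exposure is divided by its sample SD) or a
    list of indicator columns (e.g. quartile dummies).
    """
    exposures = [exposure] if isinstance(exposure, str) else list(exposure)
    covariates = covariates or []
    if cohort[event_col].sum() < 1:
        raise ValueError("no events in cohort")
    expo = cohort[exposures].astype(float).copy()
    if per_sd:
        if len(exposures) != 1:
            raise ValueError("per_sd applies to a single continuous exposure")
        sd = expo.iloc[:, 0].std(ddof=1)
        expo.iloc[:, 0] = expo.iloc[:, 0] / sd
    design = pd.concat(
        [expo, expand_covariates(cohort, covariates, reference_levels)], axis=1
    )
    constant = [c for c in design.columns if design[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"covariate constant within the risk set: {constant}")
    df = design.copy()
    df[duration_col] = cohort[duration_col].to_numpy(dtype=float)
    df[event_col] = cohort[event_col].to_numpy(dtype=int)

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as first_err:
        # near-collinear covariates with few events can leave the partial
        # likelihood flat; a weak ridge restores identifiability
        try:
            cph = CoxPHFitter(penalizer=1.0 / len(df))
            cph.fit(df, duration_col=duration_col, event_col=event_col)
            warnings.warn(
                f"Cox fit required a weak ridge (penalizer={1.0 / len(df):.2g}) "
                f"after: {first_err}"
            )
        except Exception as err:  # pragma: no cover
            raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    res = _wald_summary(cph.params_, cph.standard_errors_)
    return CoxFitResult(
        summary=res,
        loglik=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[event_col].sum()),
        model=cph,
        design=df,
    )


def test_proportional_hazards(
    fit: CoxFitResult, time_transform: str = "rank"
) -> pd.DataFrame:
    """Scaled-Schoenfeld-residual test of proportional hazards.

    Per-term chi-square tests against transformed time, plus a ``GLOBAL``
    row combining the per-term statistics (sum of chi-squares, df = number
    of terms).
    """
    if fit.n_events < 2:
        raise ValueError("proportional-hazards test undefined with < 2 events")
    res = proportional_hazard_test(fit.model, fit.design, time_transform=time_transform)
    stat = res.summary["test_statistic"]
    p = res.summary["p"]
    out = pd.DataFrame(
        {"term": stat.index.get_level_values(0), "chi2": stat.to_numpy(),
         "p": p.to_numpy()}
    )
    g_chi2 = float(out["chi2"].sum())
    g_df = len(out)
    out.loc[len(out)] = ["GLOBAL", g_chi2, float(stats.chi2.sf(g_chi2, g_df))]
    return out


def quartile_index(values: np.ndarray) -> np.ndarray:
    """Within-sample quartile index 1-4; a value exactly at a cut point goes
    to the lower quartile."""
    v = np.asarray(values, dtype=float)
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return 1 + (v > q1).astype(int) + (v > q2).astype(int) + (v > q3).astype(int)


def quartile_dummies(values: np.ndarray, prefix: str = "Q") -> pd.DataFrame:
    idx = quartile_index(values)
    return pd.DataFrame(
        {f"{prefix}{k}": (idx == k).astype(float) for k in (2, 3, 4)}
    )


def quartile_trend_test(
    cohort: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> dict:
    """P for trend across exposure quartiles: quartile index 1-4 entered as
    one continuous covariate; Wald p on its coefficient."""
    work = cohort.copy()
    work["_quartile_trend"] = quartile_index(work[exposure].to_numpy()).astype(float)
    fit = fit_cox(work, "_quartile_trend", covariates,
                  duration_col=duration_col, event_col=event_col)
    row = fit.summary.set_index("term").loc["_quartile_trend"]
    return {"loghr_per_quartile": float(row["loghr"]), "p_trend": float(row["p"]),
            "fit": fit}


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell's restricted (natural) cubic spline basis.

    For k knots returns an (n, k-1) matrix: the linear term plus k-2
    restricted truncated-power terms, each normalised by (t_k - t_1)^2 so
    the columns share the scale of x.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("coincident knots")
    k = knots.size
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def pos3(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class DoseResponseCurve:
    knots: np.ndarray
    reference: float
    grid: pd.DataFrame  # exposure, hr, ci_low, ci_high
    p_overall: float
    p_nonlinear: float
    fit: CoxFitResult = field(repr=False, default=None)


def rcs_dose_response(
    cohort: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    grid: np.ndarray | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> DoseResponseCurve:
    """Dose-response hazard-ratio curve from a restricted-cubic-spline Cox
    model with three knots at the exposure's 25th/50th/75th centiles.

    The hazard ratio is referenced to the exposure median (HR = 1 there by
    construction); the confidence band comes from the delta method on the
    spline coefficients.  ``p_nonlinear`` is the Wald test on the restricted
    cubic term, ``p_overall`` the joint Wald test on both spline terms.
    """
    x = cohort[exposure].to_numpy(dtype=float)
    knots = np.quantile(x, [0.25, 0.50, 0.75])
    if np.unique(knots).size < 3:
        raise ValueError("coincident knots: exposure too discrete for 3-knot spline")
    basis = rcs_basis(x, knots)
    work = cohort.copy()
    names = [f"_rcs{j}" for j in range(basis.shape[1])]
    for j, nm in enumerate(names):
        work[nm] = basis[:, j]
    fit = fit_cox(work, names, covariates,
                  duration_col=duration_col, event_col=event_col)

    idx = [list(fit.summary["term"]).index(nm) for nm in names]
    beta = fit.summary["loghr"].to_numpy()[idx]
    cov = np.asarray(fit.model.variance_matrix_)[np.ix_(idx, idx)]

    reference = float(knots[1])  # median
    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 101)
    gb = rcs_basis(np.asarray(grid, dtype=float), knots)
    rb = rcs_basis(np.array([reference]), knots)
    c = gb - rb  # contrast vs reference
    f = c @ beta
    var = np.einsum("ij,jk,ik->i", c, cov, c)
    se = np.sqrt(np.maximum(var, 0.0))
    curve = pd.DataFrame(
        {
            "exposure": grid,
            "hr": np.exp(f),
            "ci_low": np.exp(f - 1.959963984540054 * se),
            "ci_high": np.exp(f + 1.959963984540054 * se),
        }
    )
    # Wald tests
    chi_overall = float(beta @ np.linalg.solve(cov, beta))
    p_overall = float(stats.chi2.sf(chi_overall, len(beta)))
    b_nl = beta[1:]
    v_nl = cov[1:, 1:]
    chi_nl = float(b_nl @ np.linalg.solve(v_nl, b_nl))
    p_nonlinear = float(stats.chi2.sf(chi_nl, len(b_nl)))
    return DoseResponseCurve(
        knots=knots, reference=reference, grid=curve,
        p_overall=p_overall, p_nonlinear=p_nonlinear, fit=fit,
    )


# ---------------------------------------------------------------------------
# Fine-Gray competing risks
# ---------------------------------------------------------------------------

def _censoring_survival(time: np.ndarray, censored: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=censored)
    return km


def fine_gray_expand(
    cohort: pd.DataFrame,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
    competing_col: str = "death_event",
) -> pd.DataFrame:
    """Censoring-weighted long-format expansion for the subdistribution
    hazard (crprep-style).

    Participants with the competing event remain in later risk sets with
    inverse-probability-of-censoring weights G(t)/G(T_death); their extended
    follow-up is split at the jump times of the censoring Kaplan-Meier
    estimate.  Everyone else keeps a single (0, T] interval with weight 1.
    """
    t = cohort[duration_col].to_numpy(dtype=float)
    ev = cohort[event_col].to_numpy(dtype=int)
    cmp_ev = cohort[competing_col].to_numpy(dtype=int)
    if (ev + cmp_ev > 1).any():
        raise ValueError("a participant cannot have both event and competing event")
    censored = (ev == 0) & (cmp_ev == 0)
    km = _censoring_survival(t, censored.astype(int))
    g = km.survival_function_["KM_estimate"]
    g_times = g.index.to_numpy(dtype=float)
    g_vals = g.to_numpy(dtype=float)

    def g_at(times: np.ndarray) -> np.ndarray:
        # left-continuous G(t-): survival just before t
        idx = np.searchsorted(g_times, times, side="left") - 1
        return np.where(idx >= 0, g_vals[np.maximum(idx, 0)], 1.0)

    event_times = np.unique(t[ev == 1])
    tau_max = event_times.max() if event_times.size else t.max()
    jump_times = g_times[np.r_[g_vals[0] < 1.0, np.diff(g_vals) < 0]] if g_times.size else np.array([])

    ids = cohort.index.to_numpy()
    rows_id, rows_start, rows_stop, rows_ev, rows_w = [], [], [], [], []
    for i in range(len(cohort)):
        rows_id.append(ids[i]); rows_start.append(0.0); rows_stop.append(t[i])
        rows_ev.append(int(ev[i])); rows_w.append(1.0)
        if cmp_ev[i] == 1 and t[i] < tau_max:
            # extend through later event times, reweighting at censoring jumps
            cuts = jump_times[(jump_times > t[i]) & (jump_times < tau_max)]
            bounds = np.r_[t[i], cuts, tau_max]
            g_death = g_at(np.array([t[i]]))[0]
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                w = g_at(np.array([(a + b) / 2]))[0] / max(g_death, 1e-12)
                rows_id.append(ids[i]); rows_start.append(a); rows_stop.append(b)
                rows_ev.append(0); rows_w.append(w)
    return pd.DataFrame(
        {"_id": rows_id, "_start": rows_start, "_stop": rows_stop,
         "_event": rows_ev, "_weight": rows_w}
    )


def fit_fine_gray(
    cohort: pd.DataFrame,
    exposure: str | list[str],
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
    competing_col: str = "death_event",
    reference_levels: dict[str, str] | None = None,
) -> CoxFitResult:
    """Fine-Gray subdistribution-hazard regression, death as competing event.

    Fitted as a censoring-weighted Cox model on the crprep-style expanded
    data; with zero competing events it coincides with the cause-specific
    Cox model.  Standard errors are model-based (the IPCW weighting is
    treated as known), which is mildly conservative.
    """
    exposures = [exposure] if isinstance(exposure, str) else list(exposure)
    covariates = covariates or []
    if cohort[event_col].sum() < 1:
        raise ValueError("no events of interest: Fine-Gray fit undefined")
    long = fine_gray_expand(cohort, duration_col, event_col, competing_col)
    design = pd.concat(
        [cohort[exposures].astype(float),
         expand_covariates(cohort, covariates, reference_levels)],
        axis=1,
    )
    long = long.merge(design, left_on="_id", right_index=True, how="left")
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(long, id_col="_id", start_col="_start", stop_col="_stop",
                event_col="_event", weights_col="_weight")
    res = _wald_summary(ctv.params_, ctv.standard_errors_)
    return CoxFitResult(
        summary=res, loglik=float(ctv.log_likelihood_), n=len(cohort),
        n_events=int(cohort[event_col].sum()), model=ctv, design=long,
    )


# ---------------------------------------------------------------------------
# Sensitivity utilities
# ---------------------------------------------------------------------------

def landmark_filter(
    cohort: pd.DataFrame,
    landmark_years: float = 2.0,
    duration_col: str = "time_years",
) -> pd.DataFrame:
    """Restart follow-up at the landmark: participants whose follow-up ended
    at or before the landmark are removed; remaining times shift down by
    ``landmark_years``."""
    keep = cohort[duration_col] > landmark_years
    if not keep.any():
        warnings.warn("all follow-up ends before the landmark: empty cohort")
    out = cohort.loc[keep].copy()
    out[duration_col] = out[duration_col] - landmark_years
    return out


def subgroup_fits(
    cohort: pd.DataFrame,
    by: str,
    exposure: str,
    covariates: list[str] | None = None,
    duration_col: str = "time_years",
    event_col: str = "aaa_event",
) -> dict:
    """Stratified exposure fits plus a product-term heterogeneity p.

    Fits the exposure within each level of ``by``, then compares Cox models
    with and without exposure-by-stratum product terms by likelihood ratio.
    """
    covariates = [c for c in (covariates or []) if c != by]
    strata = {}
    for level, sub in cohort.groupby(by, observed=True):
        if sub[event_col].sum() >= 1:
            strata[level] = fit_cox(sub, exposure, covariates,
                                    duration_col=duration_col, event_col=event_col)
    work = cohort.copy()
    dummies = expand_covariates(work, [by])
    base_cols = list(dummies.columns)
    for c in base_cols:
        work[c] = dummies[c]
        work[f"{exposure}:{c}"] = work[exposure].astype(float) * dummies[c]
    null_fit = fit_cox(work, [exposure] + base_cols, covariates,
                       duration_col=duration_col, event_col=event_col)
    full_fit = fit_cox(
        work, [exposure] + base_cols + [f"{exposure}:{c}" for c in base_cols],
        covariates, duration_col=duration_col, event_col=event_col,
    )
    lr = 2.0 * (full_fit.loglik - null_fit.loglik)
    df = len(base_cols)
    p_het = float(stats.chi2.sf(max(lr, 0.0), df))
    return {"strata": strata, "p_heterogeneity": p_het}
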