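"""Biological-age estimators and the accelerated-ageing classifier.

Two biomarker-based biological-age measures are implemented:

**Klemera-Doubal biological age (KDM).**  For each of nine biomarkers an
ordinary least-squares regression of the biomarker on chronological age
(CA), fitted separately within each sex, yields an intercept ``q_i``, a
slope ``k_i`` and a residual root-mean-square error ``s_i``.  Each
biomarker then provides an implicit age estimate ``(x_i - q_i) / k_i``
whose precision is ``(k_i / s_i)^2``; chronological age itself enters as
one more estimate with precision ``1 / s_BA^2``, where ``s_BA^2`` is the
variance in CA explained by the full biomarker set.  Biological age is the
precision-weighted mean

    BA = [ sum_i (x_i - q_i) k_i / s_i^2  +  CA / s_BA^2 ]
         / [ sum_i (k_i / s_i)^2  +  1 / s_BA^2 ].

**Phenotypic age (PhenoAge).**  A fixed-coefficient linear predictor ``xb``
over nine blood biomarkers plus CA is mapped through a Gompertz mortality
model to a 10-year mortality risk, then inverted to the age at which a
reference person would carry that risk:

    mortality risk = 1 - exp(-1.51714 * exp(xb) / 0.0076927)
    PhenoAge       = 141.50 + ln(-0.00553 * ln(1 - mortality risk)) / 0.09165

**Age acceleration.**  The residual of biological age regressed on CA over
the analysis sample.  A strictly positive residual classifies a
participant as experiencing accelerated biological ageing; zero or less is
non-accelerated.  Residuals are mean-zero and uncorrelated with CA by
construction of OLS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ageaccel.simulate import KDM_BIOMARKERS, PHENOAGE_BIOMARKERS


# ---------------------------------------------------------------------------
# Klemera-Doubal biological age
# ---------------------------------------------------------------------------

@dataclass
class KDMModel:
    """Per-sex Klemera-Doubal parameters for one training stratum."""

    sex: str
    biomarker_names: list[str]
    q: np.ndarray  # intercepts, biomarker units
    k: np.ndarray  # slopes, biomarker units per year
    s: np.ndarray  # residual RMSE, biomarker units
    s_ba: float    # years; sqrt of variance in CA explained by the biomarkers

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.biomarker_names)
        if not (len(self.q) == len(self.k) == len(self.s) == n):
            raise ValueError("parameter arrays must match biomarker_names")
        if (self.s <= 0).any() or self.s_ba <= 0:
            raise ValueError("s_i and s_BA must be > 0")
        if (self.k == 0).any():
            warnings.warn("a biomarker has exactly zero age slope (uninformative)")

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "biomarker_names": list(self.biomarker_names),
            "q": self.q.tolist(),
            "k": self.k.tolist(),
            "s": self.s.tolist(),
            "s_ba": float(self.s_ba),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KDMModel":
        return cls(
            sex=d["sex"],
            biomarker_names=list(d["biomarker_names"]),
            q=np.asarray(d["q"], dtype=float),
            k=np.asarray(d["k"], dtype=float),
            s=np.asarray(d["s"], dtype=float),
            s_ba=float(d["s_ba"]),
        )


def fit_kdm_model(
    training: pd.DataFrame,
    sex: str,
    biomarkers: list[str] | None = None,
) -> KDMModel:
    """Fit one sex stratum of the Klemera-Doubal model.

    Per biomarker, OLS of the biomarker on CA gives (q_i, k_i, s_i); s_BA^2
    is the sample variance of the fitted values from a multiple OLS of CA on
    all biomarkers jointly (the variance in CA explained by the set).
    """
    biomarkers = list(biomarkers or KDM_BIOMARKERS)
    sub = training.loc[training["sex"] == sex, ["chronological_age"] + biomarkers]
    sub = sub.dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete participants in sex stratum {sex!r}")
    ca = sub["chronological_age"].to_numpy()
    if np.var(ca) == 0:
        raise ValueError("degenerate design: chronological age has zero variance")

    x_design = np.column_stack([np.ones_like(ca), ca])
    q = np.empty(len(biomarkers))
    k = np.empty(len(biomarkers))
    s = np.empty(len(biomarkers))
    for i, b in enumerate(biomarkers):
        y = sub[b].to_numpy()
        coef, *_ = np.linalg.lstsq(x_design, y, rcond=None)
        q[i], k[i] = coef
        resid = y - x_design @ coef
        s[i] = np.sqrt(np.mean(resid**2))

    bio_design = np.column_stack(
        [np.ones(len(sub))] + [sub[b].to_numpy() for b in biomarkers]
    )
    coef, *_ = np.linalg.lstsq(bio_design, ca, rcond=None)
    fitted = bio_design @ coef
    s_ba2 = float(np.var(fitted))
    if s_ba2 <= 0:
        raise ValueError("biomarkers explain no CA variance; s_BA undefined")
    return KDMModel(sex=sex, biomarker_names=biomarkers, q=q, k=k, s=s,
                    s_ba=float(np.sqrt(s_ba2)))


def predict_kdm_age(
    model: KDMModel, biomarkers: np.ndarray | pd.DataFrame, ca: np.ndarray | float
) -> np.ndarray:
    """Evaluate the KDM precision-weighted mean for one or many participants.

    ``biomarkers`` is an (n, m) array (or DataFrame with the model's
    biomarker columns) and ``ca`` the matching chronological ages.
    """
    if isinstance(biomarkers, pd.DataFrame):
        biomarkers = biomarkers[model.biomarker_names].to_numpy()
    x = np.atleast_2d(np.asarray(biomarkers, dtype=float))
    if x.shape[1] != len(model.biomarker_names):
        raise ValueError("biomarker vector length does not match model")
    if not np.isfinite(x).all():
        raise ValueError("incomplete input: missing or non-finite biomarker value")
    ca = np.asarray(ca, dtype=float)
    num = (x - model.q) @ (model.k / model.s**2) + ca / model.s_ba**2
    den = np.sum((model.k / model.s) ** 2) + 1.0 / model.s_ba**2
    out = num / den
    return out if out.ndim else float(out)


def kdm_age_for_cohort(
    cohort: pd.DataFrame, models: dict[str, KDMModel]
) -> pd.Series:
    """Apply per-sex KDM models to a cohort table."""
    out = pd.Series(np.nan, index=cohort.index, name="kdm_age")
    for sex, model in models.items():
        mask = cohort["sex"] == sex
        if mask.any():
            out.loc[mask] = predict_kdm_age(
                model,
                cohort.loc[mask, model.biomarker_names],
                cohort.loc[mask, "chronological_age"].to_numpy(),
            )
    return out


def save_kdm_models(models: dict[str, KDMModel], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({sex: m.to_dict() for sex, m in models.items()}, fh, indent=1)


def load_kdm_models(path: str) -> dict[str, KDMModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {sex: KDMModel.from_dict(d) for sex, d in raw.items()}


# ---------------------------------------------------------------------------
# Phenotypic age
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenoAgeCoefficients:
    """Published constants of the phenotypic-age closed form.

    The linear-predictor coefficients are in the original published units
    (albumin g/L, creatinine umol/L, glucose mmol/L, C-reactive protein
    mg/dL entered as its natural log, lymphocyte %, mean cell volume fL,
    red-cell distribution width %, alkaline phosphatase U/L, white cell
    count 10^9/L, chronological age years).
    """

    intercept: float = -19.907
    albumin: float = -0.0336
    creatinine: float = 0.0095
    glucose: float = 0.1953
    log_crp: float = 0.0954
    lymphocyte_pct: float = -0.0120
    mcv: float = 0.0268
    rdw: float = 0.3306
    alp: float = 0.00188
    wbc: float = 0.0554
    chronological_age: float = 0.0804
    # Gompertz mortality-model constants
    g_age_anchor: float = 141.50
    g_slope: float = 0.09165
    g_scale: float = 0.00553
    g_cumhaz: float = 1.51714
    g_rate: float = 0.0076927
    crp_floor: float = 0.01  # mg/dL, applied before the log

    @property
    def biomarker_order(self) -> list[str]:
        return list(PHENOAGE_BIOMARKERS)


def compute_phenoage(
    biomarkers: pd.DataFrame | dict,
    ca: np.ndarray | float | None = None,
    coeffs: PhenoAgeCoefficients | None = None,
    floor_crp: bool = True,
) -> pd.DataFrame:
    """Evaluate xb, the Gompertz mortality risk, and phenotypic age.

    ``biomarkers`` must contain the nine phenotypic-age biomarker columns
    (and ``chronological_age``, unless ``ca`` is passed separately).
    Returns a DataFrame with columns ``xb``, ``mortality_risk``,
    ``phenoage``.
    """
    c = coeffs or PhenoAgeCoefficients()
    if isinstance(biomarkers, dict):
        biomarkers = pd.DataFrame({k: np.atleast_1d(v) for k, v in biomarkers.items()})
    if ca is None:
        ca = biomarkers["chronological_age"].to_numpy()
    ca = np.asarray(ca, dtype=float)

    crp = np.asarray(biomarkers["crp"], dtype=float)
    if floor_crp:
        crp = np.maximum(crp, c.crp_floor)
    if (crp <= 0).any():
        raise ValueError("CRP must be > 0 to enter the log (flooring disabled)")

    cols = {b: np.asarray(biomarkers[b], dtype=float) for b in PHENOAGE_BIOMARKERS}
    if not all(np.isfinite(v).all() for v in cols.values()) or not np.isfinite(ca).all():
        raise ValueError("non-finite phenotypic-age input")

    xb = (
        c.intercept
        + c.albumin * cols["albumin"]
        + c.creatinine * cols["creatinine"]
        + c.glucose * cols["glucose"]
        + c.log_crp * np.log(crp)
        + c.lymphocyte_pct * cols["lymphocyte_pct"]
        + c.mcv * cols["mcv"]
        + c.rdw * cols["rdw"]
        + c.alp * cols["alp"]
        + c.wbc * cols["wbc"]
        + c.chronological_age * ca
    )
    mortality_risk = 1.0 - np.exp(-c.g_cumhaz * np.exp(xb) / c.g_rate)
    if ((mortality_risk <= 0.0) | (mortality_risk >= 1.0)).any():
        bad = xb[(mortality_risk <= 0.0) | (mortality_risk >= 1.0)]
        raise OverflowError(
            f"mortality risk saturated at 0 or 1 (xb extreme, e.g. {bad.flat[0]:.3g})"
        )
    phenoage = c.g_age_anchor + np.log(-c.g_scale * np.log1p(-mortality_risk)) / c.g_slope
    return pd.DataFrame(
        {"xb": xb, "mortality_risk": mortality_risk, "phenoage": phenoage}
    )


# ---------------------------------------------------------------------------
# Age acceleration
# ---------------------------------------------------------------------------

@dataclass
class AccelerationResult:
    bioage: float
    residual: float
    accelerated: bool


def compute_acceleration(
    bioages: np.ndarray, cas: np.ndarray
) -> pd.DataFrame:
    """Residual of biological age regressed on chronological age.

    Returns a DataFrame with ``bioage``, ``residual`` (years) and the
    ``accelerated`` flag (strictly positive residual).  The regression is
    fitted over the supplied sample, so residuals are mean-zero and
    uncorrelated with CA on that sample.
    """
    ba = np.asarray(bioages, dtype=float)
    ca = np.asarray(cas, dtype=float)
    if ba.shape != ca.shape:
        raise ValueError("bioages and CAs must have the same shape")
    if ba.size < 3:
        raise ValueError("need >= 3 pairs to fit the acceleration regression")
    if np.var(ca) == 0:
        raise ValueError("chronological age has zero variance")
    design = np.column_stack([np.ones_like(ca), ca])
    coef, *_ = np.linalg.lstsq(design, ba, rcond=None)
    resid = ba - design @ coef
    # snap numerical dust to exact zero so the strict > 0 rule classifies
    # participants on the identity line as non-accelerated
    resid[np.abs(resid) < 1e-10 * max(1.0, float(np.abs(ba).max()))] = 0.0
    return pd.DataFrame(
        {"bioage": ba, "residual": resid, "accelerated": resid > 0}
    )


def score_cohort(
    cohort: pd.DataFrame, kdm_models: dict[str, KDMModel],
    coeffs: PhenoAgeCoefficients | None = None,
) -> pd.DataFrame:
    """Attach kdm_age, phenoage and both acceleration columns to a cohort."""
    out = cohort.copy()
    out["kdm_age"] = kdm_age_for_cohort(out, kdm_models)
    pheno = compute_phenoage(out, coeffs=coeffs)
    out["phenoage"] = pheno["phenoage"].to_numpy()
    ca = out["chronological_age"].to_numpy()
    for score in ("kdm", "phenoage"):
        col = "kdm_age" if score == "kdm" else "phenoage"
        acc = compute_acceleration(out[col].to_numpy(), ca)
        out[f"{score}_accel"] = acc["residual"].to_numpy()
        out[f"{score}_accelerated"] = acc["accelerated"].to_numpy().astype(int)
    return out
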