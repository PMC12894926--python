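"""Weighted polygenic risk score and tertile-based genetic risk groups.

The score aggregates effect-allele dosages over N independent risk
variants, weighted by their per-allele log odds ratios and rescaled so the
score is on an allele-count-like scale:

    weighted PRS = sum_i beta_i * dosage_i * N / sum_i beta_i

The rescaling makes the score invariant to a common multiplicative factor
in the weights, and reduces to the plain allele count when all weights are
equal.  Participants are grouped into low / intermediate / high genetic
risk at the sample tertiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RISK_LABELS = ("low", "intermediate", "high")


@dataclass
class PRSWeights:
    snp_ids: list[str]
    effect_alleles: list[str]
    betas: np.ndarray  # per-allele log odds ratios

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if not (len(self.snp_ids) == len(self.effect_alleles) == len(self.betas)):
            raise ValueError("snp_ids, effect_alleles and betas must align")
        if self.betas.sum() == 0:
            raise ValueError("Sum(beta) = 0: weighted PRS normalisation undefined")

    @property
    def n(self) -> int:
        return len(self.betas)

    @classmethod
    def from_tsv(cls, path: str) -> "PRSWeights":
        tab = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=tab["snp_id"].astype(str).tolist(),
            effect_alleles=tab["effect_allele"].astype(str).tolist(),
            betas=tab["beta"].to_numpy(dtype=float),
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"snp_id": self.snp_ids, "effect_allele": self.effect_alleles,
             "beta": self.betas}
        ).to_csv(path, sep="\t", index=False)


def default_weights(betas: np.ndarray) -> PRSWeights:
    """Wrap a beta vector with synthetic SNP ids and effect alleles."""
    betas = np.asarray(betas, dtype=float)
    return PRSWeights(
        snp_ids=[f"rs_synth_{i:02d}" for i in range(len(betas))],
        effect_alleles=["A"] * len(betas),
        betas=betas,
    )


def compute_weighted_prs(
    weights: PRSWeights, dosages: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Weighted PRS per participant from an (n, N) dosage matrix in [0, 2]."""
    if isinstance(dosages, pd.DataFrame):
        dosages = dosages.to_numpy(dtype=float)
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    if d.shape[1] != weights.n:
        raise ValueError("dosage matrix width does not match number of SNPs")
    if np.isnan(d).any():
        raise ValueError("missing dosage; impute first (impute_missing_dosage)")
    if ((d < 0) | (d > 2)).any():
        raise ValueError("dosages must lie in [0, 2]")
    score = d @ weights.betas * weights.n / weights.betas.sum()
    return score


def assign_genetic_risk_groups(
    scores: np.ndarray,
) -> tuple[pd.Categorical, tuple[float, float]]:
    """Tertile cut points and low/intermediate/high labels.

    A score exactly at a cut point goes to the lower group.  Heavy ties
    spanning a cut point trigger a warning reporting the realised group
    sizes.
    """
    s = np.asarray(scores, dtype=float)
    if np.unique(s).size < 3:
        warnings.warn("fewer than 3 distinct scores: tertile grouping degenerate")
    q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
    idx = np.where(s <= q1, 0, np.where(s <= q2, 1, 2))
    sizes = np.bincount(idx, minlength=3)
    if np.unique(s).size >= 3 and (sizes.max() - sizes.min()) > 0.1 * s.size + 1:
        warnings.warn(f"ties span a tertile cut point; group sizes {sizes.tolist()}")
    labels = pd.Categorical.from_codes(idx, categories=list(RISK_LABELS), ordered=True)
    return labels, (float(q1), float(q2))


def impute_missing_dosage(
    dosages: pd.DataFrame, weights: PRSWeights | None = None
) -> pd.DataFrame:
    """Replace missing dosages with twice the cohort effect-allele frequency
    (the observed dosage mean) for that SNP."""
    out = dosages.copy()
    for j, col in enumerate(out.columns):
        v = out[col]
        if v.isna().all():
            name = weights.snp_ids[j] if weights is not None else str(col)
            raise ValueError(f"all dosages missing for SNP {name}: frequency undefined")
        if v.isna().any():
            out[col] = v.fillna(v.mean())
    return out


def load_vcf_dosages(path: str, weights: PRSWeights) -> pd.DataFrame:
    """Minimal VCF importer: effect-allele dosage per sample and SNP.

    Uses the DS FORMAT field when present, otherwise counts effect alleles
    from GT.  When the effect allele is the VCF REF allele, the dosage is
    flipped (2 - alt count).  Variants are matched by ID.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    wanted = {sid: (i, weights.effect_alleles[i]) for i, sid in enumerate(weights.snp_ids)}
    for var in vcf:
        if var.ID not in wanted:
            continue
        _, eff = wanted[var.ID]
        dosage = None
        try:
            ds = var.format("DS")
            if ds is not None:
                cand = np.asarray(ds, dtype=float).reshape(-1)
                if cand.size == len(samples) and np.isfinite(cand).all():
                    dosage = cand
        except (KeyError, TypeError, ValueError):
            pass
        if dosage is None:
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
            gts = np.asarray(var.gt_types)
            dosage = np.select([gts == 0, gts == 1, gts == 3],
                               [0.0, 1.0, 2.0], default=np.nan)
        if eff == var.REF:
            dosage = 2.0 - dosage
        elif var.ALT and eff != var.ALT[0]:
            raise ValueError(f"effect allele {eff} matches neither REF nor ALT for {var.ID}")
        cols[var.ID] = dosage
    missing = [sid for sid in weights.snp_ids if sid not in cols]
    if missing:
        raise ValueError(f"variants absent from VCF: {missing}")
    return pd.DataFrame({sid: cols[sid] for sid in weights.snp_ids}, index=samples)
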