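"""Main survival models: age acceleration and incident AAA.

For each biological-age measure: adjusted hazard ratios for the binary
accelerated-ageing flag, per-SD continuous acceleration, acceleration
quartiles with a 1-4 trend test, a Schoenfeld proportional-hazards check,
and a three-knot restricted-cubic-spline dose-response curve referenced
to the median.
"""

from pathlib import Path

import pandas as pd

from ageaccel import io as aio
from ageaccel.pipeline import DEFAULT_COVARIATES
from ageaccel.survival import (
    fit_cox,
    quartile_dummies,
    quartile_trend_test,
    rcs_dose_response,
    test_proportional_hazards,
)

OUT = Path(__file__).resolve().parents[1] / "results"
scored = aio.read_cohort(OUT / "cohort_scored.tsv")
covs = [c for c in DEFAULT_COVARIATES if c in scored.columns]

rows = []
for score in ("kdm", "phenoage"):
    accel, flag = f"{score}_accel", f"{score}_accelerated"
    fit_bin = fit_cox(scored, flag, covs)
    fit_sd = fit_cox(scored, accel, covs, per_sd=True)
    qd = quartile_dummies(scored[accel].to_numpy(), prefix=f"{score}_q")
    fit_q = fit_cox(pd.concat([scored, qd], axis=1), list(qd.columns), covs)
    trend = quartile_trend_test(scored, accel, covs)
    ph = test_proportional_hazards(fit_bin)
    rcs = rcs_dose_response(scored, accel, covs)
    rcs.grid.to_csv(OUT / f"dose_response_{score}.tsv", sep="\t", index=False)

    b = fit_bin.summary.set_index("term").loc[flag]
    s = fit_sd.summary.set_index("term").loc[accel]
    print(f"{score}: accelerated HR {b.hr:.2f} ({b.ci_low:.2f}-{b.ci_high:.2f}), "
          f"per-SD HR {s.hr:.2f}, trend p {trend['p_trend']:.3g}, "
          f"RCS non-linearity p {rcs.p_nonlinear:.2f}, "
          f"PH global p {ph.loc[ph.term == 'GLOBAL', 'p'].iloc[0]:.2f}")
    for frame, label in ((fit_bin, "accelerated"), (fit_sd, "per_sd")):
        r = frame.summary.set_index("term").iloc[0]
        rows.append({"score": score, "term": label, "hr": r.hr,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p})
    for _, r in fit_q.summary.iterrows():
        if r.term.startswith(f"{score}_q"):
            rows.append({"score": score, "term": r.term, "hr": r.hr,
                         "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p})

aio.write_tidy_tsv(pd.DataFrame(rows), OUT / "main_hazard_ratios.tsv")
print(f"wrote {OUT / 'main_hazard_ratios.tsv'}")
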