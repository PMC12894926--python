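"""Cohort and results serialisation with strict schema checks.

Cohort tables round-trip as TSV in a fixed, documented column order;
results are written as tidy TSV and JSON carrying a ``schema_version``
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

SEX_LEVELS = {"male", "female"}


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV and validate core schema.

    Checks sex levels, non-negative follow-up, 0/1 event flags mutually
    exclusive, and dosages within [0, 2]; raises with row context.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "chronological_age", "sex", "time_years",
                "aaa_event", "death_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing required columns: {sorted(missing)}")
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    if bad_sex.any():
        row = int(df.index[bad_sex][0])
        raise ValueError(
            f"malformed sex level {df.loc[row, 'sex']!r} at row {row}"
        )
    if (df["time_years"] < 0).any():
        row = int(df.index[df["time_years"] < 0][0])
        raise ValueError(f"negative follow-up time at row {row}")
    ev = df["aaa_event"].astype(int) + df["death_event"].astype(int)
    if (ev > 1).any():
        row = int(df.index[ev > 1][0])
        raise ValueError(f"both AAA and death recorded at row {row}")
    snp_cols = [c for c in df.columns if c.startswith("snp_")]
    if snp_cols:
        d = df[snp_cols].to_numpy(dtype=float)
        out_of_range = (d < 0) | (d > 2)
        if np.any(out_of_range & np.isfinite(d)):
            r, c = np.argwhere(out_of_range & np.isfinite(d))[0]
            raise ValueError(
                f"dosage outside [0, 2] at row {int(r)}, column {snp_cols[int(c)]}"
            )
    return df


def write_results_json(obj: dict, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)


def write_tidy_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table = table.copy()
    table["schema_version"] = SCHEMA_VERSION
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
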