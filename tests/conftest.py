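import dataclasses

import numpy as np
import pandas as pd
import pytest

from ageaccel.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """Shared 12,000-participant cohort with an elevated event rate so
    survival fits have enough events for stable estimates."""
    cfg = default_config(n_participants=12_000, seed=11)
    cfg = dataclasses.replace(
        cfg,
        hazard_params=dataclasses.replace(cfg.hazard_params, baseline_rate=2.0e-3),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(n_participants=5_000, seed=5)


def _simulate_survival(
    n, seed, loghr=0.5, baseline=4e-3, censor=13.7, exposure="binary",
    extra_cols=None,
):
    """Simple purpose-built survival simulator independent of the cohort
    generator: exponential times under a log-linear hazard in one exposure."""
    rng = np.random.default_rng(seed)
    if exposure == "binary":
        x = rng.integers(0, 2, n).astype(float)
    else:
        x = rng.normal(size=n)
    lam = baseline * np.exp(loghr * x)
    t = rng.exponential(1.0 / lam)
    e = (t < censor).astype(int)
    t = np.minimum(t, censor)
    df = pd.DataFrame({"x": x, "time_years": t, "aaa_event": e})
    if extra_cols:
        for name, vals in extra_cols.items():
            df[name] = vals
    return df


@pytest.fixture(scope="session")
def simulate_survival():
    """The simple one-exposure survival simulator, as a callable fixture."""
    return _simulate_survival
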