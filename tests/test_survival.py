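import dataclasses
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ageaccel.simulate import default_config, simulate_cohort
from ageaccel.survival import (
    fit_cox,
    fit_fine_gray,
    landmark_filter,
    quartile_index,
    quartile_trend_test,
    rcs_basis,
    rcs_dose_response,
    subgroup_fits,
)
from ageaccel.survival import test_proportional_hazards as schoenfeld_ph_test


class TestFitCox:
    def test_recovers_binary_loghr_single_replicate(self, simulate_survival):
        df = simulate_survival(20_000, seed=0, loghr=0.5)
        fit = fit_cox(df, "x")
        assert fit.loghr("x") == pytest.approx(0.5, abs=0.1)
        row = fit.summary.set_index("term").loc["x"]
        assert row.ci_low < np.exp(0.5) < row.ci_high

    def test_per_sd_scaling_is_exact_reparameterization(self, simulate_survival):
        df = simulate_survival(4_000, seed=1, loghr=0.3, exposure="continuous")
        raw = fit_cox(df, "x")
        scaled = fit_cox(df, "x", per_sd=True)
        sd = df["x"].std(ddof=1)
        assert scaled.loghr("x") == pytest.approx(raw.loghr("x") * sd, rel=1e-6)

    def test_categorical_covariate_expanded_against_reference(self, simulate_survival):
        df = simulate_survival(3_000, seed=2)
        df["grp"] = np.random.default_rng(0).choice(["a", "b", "c"], 3_000)
        fit = fit_cox(df, "x", ["grp"], reference_levels={"grp": "a"})
        terms = set(fit.summary.term)
        assert {"grp[b]", "grp[c]"} <= terms and "grp[a]" not in terms

    def test_constant_covariate_rejected(self, simulate_survival):
        df = simulate_survival(500, seed=3)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fit_cox(df, "x", ["flat"])

    def test_no_events_rejected(self, simulate_survival):
        df = simulate_survival(200, seed=4)
        df["aaa_event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, "x")


class TestProportionalHazards:
    def test_time_varying_effect_detected(self):
        # effect that decays in time violates proportionality
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.integers(0, 2, n).astype(float)
        # piecewise hazard: strong early effect, none later
        t_early = rng.exponential(1 / (8e-3 * np.exp(2.0 * x)))
        t_late = 2.0 + rng.exponential(1 / 8e-3, n)
        t = np.where(t_early < 2.0, t_early, t_late)
        e = (t < 13.7).astype(int)
        df = pd.DataFrame({"x": x, "time_years": np.minimum(t, 13.7),
                           "aaa_event": e})
        fit = fit_cox(df, "x")
        ph = schoenfeld_ph_test(fit)
        assert float(ph.loc[ph.term == "x", "p"].iloc[0]) < 0.05

    def test_single_event_rejected(self, simulate_survival):
        df = simulate_survival(200, seed=6)
        df["aaa_event"] = 0
        df.loc[0, "aaa_event"] = 1
        fit_df = df.copy()
        with pytest.raises(ValueError):
            fit = fit_cox(fit_df, "x")
            schoenfeld_ph_test(fit)


class TestQuartiles:
    def test_boundaries_one_to_eight(self):
        assert quartile_index(np.arange(1.0, 9.0)).tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_monotone_effect_yields_small_trend_p(self, simulate_survival):
        df = simulate_survival(20_000, seed=7, loghr=0.4, exposure="continuous")
        out = quartile_trend_test(df, "x")
        assert out["p_trend"] < 0.05
        assert out["loghr_per_quartile"] > 0


class TestRCS:
    def test_basis_shape_and_linearity_beyond_last_knot(self):
        knots = np.array([-1.0, 0.0, 1.0])
        x = np.linspace(-3, 3, 200)
        b = rcs_basis(x, knots)
        assert b.shape == (200, 2)
        # restricted: second derivative ~0 beyond boundary knots
        tail = x > 1.5
        second = np.diff(b[tail, 1], 2)
        assert np.abs(second).max() < 1e-9

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError, match="knot"):
            rcs_basis(np.arange(5.0), np.array([1.0, 1.0, 2.0]))

    def test_hr_is_exactly_one_at_reference_median(self, simulate_survival):
        df = simulate_survival(4_000, seed=8, loghr=0.3, exposure="continuous")
        curve = rcs_dose_response(df, "x", grid=np.array([np.median(df["x"])]))
        assert curve.grid["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert curve.reference == pytest.approx(np.median(df["x"]))

    def test_quadratic_hazard_detected_as_nonlinear(self):
        rng = np.random.default_rng(9)
        n = 20_000
        x = rng.normal(size=n)
        lam = 4e-3 * np.exp(0.25 * x + 0.25 * x**2)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"x": x, "time_years": np.minimum(t, 13.7),
                           "aaa_event": (t < 13.7).astype(int)})
        curve = rcs_dose_response(df, "x")
        assert curve.p_nonlinear < 0.05
        assert curve.p_overall < 0.05


class TestFineGray:
    def _no_death_cohort(self, n=6_000, seed=3):
        cfg = default_config(n_participants=n, seed=seed, death_rate=0.0)
        cfg = dataclasses.replace(
            cfg, hazard_params=dataclasses.replace(cfg.hazard_params,
                                                   baseline_rate=1.5e-3),
        )
        co = simulate_cohort(cfg)
        co["expo"] = (co.true_acceleration > 0).astype(int)
        return co

    def test_equals_cause_specific_cox_without_competing_events(self):
        co = self._no_death_cohort()
        f_cox = fit_cox(co, "expo", ["chronological_age"])
        f_fg = fit_fine_gray(co, "expo", ["chronological_age"])
        assert np.abs(
            f_cox.summary.loghr.to_numpy() - f_fg.summary.loghr.to_numpy()
        ).max() < 1e-6

    def test_heavy_competing_mortality_attenuates_subdistribution_hr(self):
        cfg = default_config(n_participants=8_000, seed=10, death_rate=0.06)
        cfg = dataclasses.replace(
            cfg, hazard_params=dataclasses.replace(cfg.hazard_params,
                                                   baseline_rate=2e-3),
        )
        co = simulate_cohort(cfg)
        co["expo"] = (co.true_acceleration > 0).astype(int)
        cs = fit_cox(co, "expo", [])
        fg = fit_fine_gray(co, "expo", [])
        assert fg.loghr("expo") < cs.loghr("expo")

    def test_no_events_rejected(self):
        co = self._no_death_cohort(n=300, seed=4)
        co["aaa_event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_fine_gray(co, "expo")

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_cross_check_against_cmprsk_crr(self, tmp_path):
        """Independent oracle: the crr estimator from the cmprsk R package
        on the same small dataset."""
        cfg = default_config(n_participants=1_200, seed=12, death_rate=0.05)
        cfg = dataclasses.replace(
            cfg, hazard_params=dataclasses.replace(cfg.hazard_params,
                                                   baseline_rate=4e-3),
        )
        co = simulate_cohort(cfg)
        co["expo"] = (co.true_acceleration > 0).astype(float)
        ours = fit_fine_gray(co, "expo", [])
        dat = co[["time_years", "aaa_event", "death_event", "expo"]]
        csv = tmp_path / "d.csv"
        dat.to_csv(csv, index=False)
        script = tmp_path / "crr.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(cmprsk))
            d <- read.csv("{csv}")
            fstatus <- ifelse(d$aaa_event == 1, 1, ifelse(d$death_event == 1, 2, 0))
            fit <- crr(d$time_years, fstatus, cov1 = cbind(expo = d$expo))
            cat(fit$coef, "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        crr_coef = float(out.stdout.strip().split()[-1])
        assert ours.loghr("expo") == pytest.approx(crr_coef, abs=0.05)


class TestLandmarkAndSubgroups:
    def test_toy_enumeration(self):
        df = pd.DataFrame({"time_years": [1.0, 5.0], "aaa_event": [1, 1]})
        out = landmark_filter(df, 2.0)
        assert len(out) == 1
        assert out.time_years.iloc[0] == pytest.approx(3.0)

    def test_landmark_zero_is_identity(self):
        df = pd.DataFrame({"time_years": [1.0, 5.0], "aaa_event": [1, 0]})
        pd.testing.assert_frame_equal(landmark_filter(df, 0.0), df)

    def test_all_events_before_landmark_warns_empty(self):
        df = pd.DataFrame({"time_years": [1.0, 1.5], "aaa_event": [1, 1]})
        with pytest.warns(UserWarning, match="empty"):
            out = landmark_filter(df, 2.0)
        assert len(out) == 0

    def test_complete_case_equals_never_missing(self, medium_cohort):
        co = medium_cohort.copy()
        co["expo"] = (co.true_acceleration > 0).astype(int)
        rng = np.random.default_rng(0)
        holes = rng.random(len(co)) < 0.1
        co_miss = co.copy()
        co_miss.loc[holes, "bmi"] = np.nan
        cc = co_miss.dropna(subset=["bmi"])
        direct = co.loc[~holes]
        f1 = fit_cox(cc, "expo", ["bmi"])
        f2 = fit_cox(direct, "expo", ["bmi"])
        assert np.allclose(f1.summary.loghr, f2.summary.loghr)

    def test_subgroup_heterogeneity_p_in_unit_interval(self, medium_cohort):
        co = medium_cohort.copy()
        co["expo"] = (co.true_acceleration > 0).astype(float)
        out = subgroup_fits(co, "sex", "expo", ["chronological_age"])
        assert 0.0 <= out["p_heterogeneity"] <= 1.0
        assert set(out["strata"]) == {"male", "female"}
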