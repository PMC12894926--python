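import numpy as np
import pandas as pd
import pytest

from ageaccel.bioage import (
    KDMModel,
    PhenoAgeCoefficients,
    compute_acceleration,
    compute_phenoage,
    fit_kdm_model,
    load_kdm_models,
    predict_kdm_age,
    save_kdm_models,
)
from ageaccel.simulate import KDM_BIOMARKERS, default_config, simulate_cohort

# frozen from a 50-digit arbitrary-precision evaluation of the closed form
# at the reference vector (albumin 45, creatinine 70, glucose 5, CRP 1,
# lymphocyte 30, MCV 90, RDW 13, ALP 70, WBC 6, CA 60)
GOLDEN_XB = -8.1397
GOLDEN_RISK = 0.055909646317301565
GOLDEN_PHENOAGE = 53.633583980640255

REFERENCE_INPUT = {
    "albumin": 45.0, "creatinine": 70.0, "glucose": 5.0, "crp": 1.0,
    "lymphocyte_pct": 30.0, "mcv": 90.0, "rdw": 13.0, "alp": 70.0, "wbc": 6.0,
}


class TestKDM:
    def test_slope_recovery_from_generator_truth(self):
        cfg = default_config(n_participants=50_000, seed=13)
        cohort = simulate_cohort(cfg)
        for sex in ("male", "female"):
            model = fit_kdm_model(cohort, sex)
            sub = cohort[cohort.sex == sex]
            sd_ca = sub.chronological_age.std()
            for i, b in enumerate(model.biomarker_names):
                spec = cfg.biomarker_specs[b]
                se = spec.noise_sd / (np.sqrt(len(sub)) * sd_ca)
                # smoking displacement inflates the marginal slope slightly;
                # allow 3 SE plus that deterministic shift
                shift = abs(spec.smoking_slope) * 0.6
                assert abs(model.k[i] - spec.age_slope) < 3 * se + shift, b

    def test_fit_is_deterministic(self):
        cohort = simulate_cohort(default_config(n_participants=2_000, seed=3))
        a = fit_kdm_model(cohort, "female")
        b = fit_kdm_model(cohort, "female")
        assert np.array_equal(a.q, b.q) and np.array_equal(a.k, b.k)
        assert a.s_ba == b.s_ba

    def test_noise_free_limit_gives_near_zero_rmse_and_sba_to_var_ca(self):
        rng = np.random.default_rng(0)
        n = 2_000
        ca = rng.uniform(40, 70, n)
        cfg = default_config(n_participants=2)
        rows = {"chronological_age": ca, "sex": ["male"] * n}
        for b in KDM_BIOMARKERS:
            s = cfg.biomarker_specs[b]
            rows[b] = s.intercept + s.age_slope * ca  # no noise
        df = pd.DataFrame(rows)
        model = fit_kdm_model(df, "male")
        assert model.s.max() < 1e-6
        assert model.s_ba ** 2 == pytest.approx(np.var(ca), rel=1e-6)

    def test_zero_ca_variance_rejected(self):
        cohort = simulate_cohort(default_config(n_participants=500, seed=1))
        cohort["chronological_age"] = 50.0
        with pytest.raises(ValueError, match="variance"):
            fit_kdm_model(cohort, "male")

    def test_prediction_on_the_biomarker_age_line_returns_ca(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = KDMModel(
                sex="male",
                biomarker_names=[f"b{i}" for i in range(9)],
                q=rng.normal(50, 10, 9),
                k=rng.uniform(0.05, 1.0, 9) * rng.choice([-1, 1], 9),
                s=rng.uniform(0.5, 5.0, 9),
                s_ba=rng.uniform(2, 15),
            )
            a = rng.uniform(30, 80)
            x = m.q + m.k * a
            assert predict_kdm_age(m, x, a) == pytest.approx(a, abs=1e-9)

    def test_single_biomarker_hand_example(self):
        m = KDMModel(sex="male", biomarker_names=["b"], q=[0.0], k=[1.0],
                     s=[1.0], s_ba=1.0)
        assert predict_kdm_age(m, [60.0], 50.0) == pytest.approx(55.0)

    def test_large_sba_limit_ignores_ca(self):
        m = KDMModel(sex="male", biomarker_names=["b"], q=[10.0], k=[2.0],
                     s=[1.0], s_ba=1e9)
        assert predict_kdm_age(m, [90.0], 123.0) == pytest.approx(40.0, abs=1e-6)

    def test_missing_biomarker_rejected(self):
        m = KDMModel(sex="male", biomarker_names=["b"], q=[0.0], k=[1.0],
                     s=[1.0], s_ba=1.0)
        with pytest.raises(ValueError, match="incomplete"):
            predict_kdm_age(m, [np.nan], 50.0)

    def test_json_round_trip(self, tmp_path):
        cohort = simulate_cohort(default_config(n_participants=1_000, seed=4))
        models = {s: fit_kdm_model(cohort, s) for s in ("male", "female")}
        path = tmp_path / "kdm.json"
        save_kdm_models(models, path)
        loaded = load_kdm_models(path)
        for s in models:
            assert np.allclose(models[s].q, loaded[s].q)
            assert models[s].s_ba == pytest.approx(loaded[s].s_ba)


class TestPhenoAge:
    def test_golden_reference_value(self):
        out = compute_phenoage(REFERENCE_INPUT, ca=60.0)
        assert out["xb"].iloc[0] == pytest.approx(GOLDEN_XB, abs=1e-9)
        assert out["mortality_risk"].iloc[0] == pytest.approx(GOLDEN_RISK, abs=1e-9)
        assert out["phenoage"].iloc[0] == pytest.approx(GOLDEN_PHENOAGE, abs=1e-9)

    def test_strictly_increasing_in_chronological_age(self):
        a = compute_phenoage(REFERENCE_INPUT, ca=60.0)["phenoage"].iloc[0]
        b = compute_phenoage(REFERENCE_INPUT, ca=61.0)["phenoage"].iloc[0]
        assert b > a

    def test_inverse_consistency_from_returned_risk(self):
        c = PhenoAgeCoefficients()
        out = compute_phenoage(REFERENCE_INPUT, ca=55.0)
        m = out["mortality_risk"].iloc[0]
        back = c.g_age_anchor + np.log(-c.g_scale * np.log(1 - m)) / c.g_slope
        assert back == pytest.approx(out["phenoage"].iloc[0], abs=1e-9)

    def test_mortality_risk_in_unit_interval_for_moderate_xb(self):
        rng = np.random.default_rng(1)
        base = dict(REFERENCE_INPUT)
        for _ in range(100):
            base["crp"] = float(rng.lognormal(-1, 1))
            base["rdw"] = float(rng.uniform(11, 16))
            out = compute_phenoage(base, ca=float(rng.uniform(40, 70)))
            assert 0.0 < out["mortality_risk"].iloc[0] < 1.0

    def test_crp_floor_and_domain_error(self):
        low = dict(REFERENCE_INPUT, crp=1e-6)
        floored = dict(REFERENCE_INPUT, crp=0.01)
        assert compute_phenoage(low, ca=60.0)["phenoage"].iloc[0] == pytest.approx(
            compute_phenoage(floored, ca=60.0)["phenoage"].iloc[0]
        )
        with pytest.raises(ValueError):
            compute_phenoage(dict(REFERENCE_INPUT, crp=-1.0), ca=60.0,
                             floor_crp=False)

    def test_extreme_xb_raises_overflow_error(self):
        with pytest.raises(OverflowError):
            compute_phenoage(dict(REFERENCE_INPUT, rdw=200.0), ca=60.0)


class TestAcceleration:
    def test_identity_line_gives_zero_residuals(self):
        ca = np.linspace(40, 70, 20)
        out = compute_acceleration(ca, ca)
        assert np.abs(out["residual"]).max() < 1e-10
        assert not out["accelerated"].any()

    def test_three_point_hand_ols(self):
        # OLS through (50,50),(60,62),(70,68): BA = 6 + 0.9*CA,
        # residuals (-1, +2, -1)
        out = compute_acceleration(np.array([50.0, 62.0, 68.0]),
                                   np.array([50.0, 60.0, 70.0]))
        assert np.allclose(out["residual"], [-1.0, 2.0, -1.0], atol=1e-9)
        assert out["accelerated"].tolist() == [False, True, False]

    def test_residuals_mean_zero_and_uncorrelated_with_ca(self):
        rng = np.random.default_rng(5)
        ca = rng.uniform(40, 70, 5_000)
        ba = 3 + 1.1 * ca + rng.normal(0, 4, ca.size)
        out = compute_acceleration(ba, ca)
        assert abs(out["residual"].mean()) < 1e-8 * out["bioage"].abs().mean()
        assert abs(np.corrcoef(out["residual"], ca)[0, 1]) < 1e-8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_acceleration(np.ones(4), np.ones(5))
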