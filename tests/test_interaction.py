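import numpy as np
import pandas as pd
import pytest

from ageaccel.interaction import (
    build_joint_groups,
    build_joint_groups_quartile,
    estimate_additive_interaction,
    joint_group_hrs,
    reri_ap_from_hrs,
)
from ageaccel.interaction import (
    test_multiplicative_interaction as multiplicative_lrt,
)


def simulate_joint(n, seed, rr10=1.0, rr01=1.0, rr11=None, base=5e-3):
    """Binary exposure x binary risk cohort with additive or multiplicative
    structure on the rate scale; rr11 defaults to rr10*rr01 (no additive or
    multiplicative interaction beyond multiplicativity)."""
    rng = np.random.default_rng(seed)
    e = rng.integers(0, 2, n).astype(float)
    g = rng.integers(0, 2, n).astype(float)
    rr11 = rr10 * rr01 if rr11 is None else rr11
    rate = base * np.where(
        (e == 1) & (g == 1), rr11,
        np.where(e == 1, rr10, np.where(g == 1, rr01, 1.0)),
    )
    t = rng.exponential(1 / rate)
    df = pd.DataFrame(
        {"expo": e, "risk": g, "time_years": np.minimum(t, 13.7),
         "aaa_event": (t < 13.7).astype(int)}
    )
    return df


class TestFormulaLayer:
    def test_hand_arithmetic(self):
        out = reri_ap_from_hrs(2.0, 3.0, 6.0)
        assert out["reri"] == pytest.approx(2.0)
        assert out["ap"] == pytest.approx(1 / 3)

    def test_null_identity(self):
        out = reri_ap_from_hrs(1.0, 1.0, 1.0)
        assert out["reri"] == 0.0 and out["ap"] == 0.0

    def test_ap_is_reri_over_hr11_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h10, h01, h11 = rng.uniform(0.2, 5.0, 3)
            out = reri_ap_from_hrs(h10, h01, h11)
            assert out["ap"] == pytest.approx(out["reri"] / h11, rel=1e-12)


class TestJointGroups:
    def test_reference_and_ordering(self):
        acc = np.array([False, True, False, True])
        risk = np.array(["low", "low", "high", "high"])
        joint = build_joint_groups(acc, risk)
        assert joint.categories[0] == "low|non_accelerated"
        assert joint[3] == "high|accelerated"
        assert joint.categories[-1] == "high|accelerated"

    def test_quartile_variant_reference(self):
        joint = build_joint_groups_quartile(np.array([1, 4]),
                                            np.array(["low", "high"]))
        assert joint.categories[0] == "low|Q1"
        assert joint[1] == "high|Q4"

    def test_joint_hr_table_reference_absent(self):
        df = simulate_joint(6_000, 1, rr10=2.0, rr01=2.0)
        joint = build_joint_groups(df.expo.astype(bool).to_numpy(),
                                   np.where(df.risk == 1, "high", "low"))
        fit = joint_group_hrs(df, joint)
        assert not any("low|non_accelerated" in t for t in fit.summary.term)


class TestAdditiveInteraction:
    def test_null_simulation_ci_covers_zero(self):
        df = simulate_joint(15_000, 2, rr10=1.0, rr01=1.0, rr11=1.0)
        res = estimate_additive_interaction(df, "expo", "risk", n_boot=200, seed=0)
        assert res.reri_ci[0] <= 0.0 <= res.reri_ci[1]
        assert abs(res.reri) < 0.5
        assert not res.additive_interaction_significant

    def test_ap_identity_holds_on_fit(self):
        df = simulate_joint(8_000, 3, rr10=2.0, rr01=1.5, rr11=4.0)
        res = estimate_additive_interaction(df, "expo", "risk", n_boot=50, seed=0)
        assert res.ap == pytest.approx(res.reri / res.hr11, rel=1e-12)

    def test_bootstrap_reproducible_for_fixed_seed(self):
        df = simulate_joint(4_000, 4, rr10=2.0, rr01=2.0)
        a = estimate_additive_interaction(df, "expo", "risk", n_boot=60, seed=9)
        b = estimate_additive_interaction(df, "expo", "risk", n_boot=60, seed=9)
        assert a.reri_ci == b.reri_ci and a.ap_ci == b.ap_ci

    def test_empty_cross_class_names_cell(self):
        df = simulate_joint(2_000, 5)
        df.loc[(df.expo == 1) & (df.risk == 1), "aaa_event"] = 0
        with pytest.raises(ValueError, match="exposure=1, highrisk=1"):
            estimate_additive_interaction(df, "expo", "risk", n_boot=10, seed=0)

    def test_non_binary_flags_rejected(self):
        df = simulate_joint(500, 6)
        df["expo"] = df["expo"] * 2.0
        with pytest.raises(ValueError, match="binary"):
            estimate_additive_interaction(df, "expo", "risk", n_boot=10, seed=0)


class TestMultiplicativeInteraction:
    def test_symmetric_cells_give_p_one(self):
        # deterministic, fully symmetric 2x2 cohort: all coefficients are 0
        # and the product term adds nothing, so the LRT sits at its boundary
        rows = []
        for e in (0, 1):
            for g in (0, 1):
                for t, ev in [(1.0, 1), (2.0, 1)] + [(5.0, 0)] * 8:
                    rows.append({"expo": float(e), "risk": float(g),
                                 "time_years": t, "aaa_event": ev})
        df = pd.DataFrame(rows)
        out = multiplicative_lrt(df, "expo", "risk")
        assert out["lrt"] == pytest.approx(0.0, abs=1e-8)
        assert out["p"] == pytest.approx(1.0)

    def test_strong_product_term_detected(self):
        df = simulate_joint(20_000, 7, rr10=1.5, rr01=1.5, rr11=6.0)
        out = multiplicative_lrt(df, "expo", "risk")
        assert out["p"] < 0.05

    def test_categorical_risk_uses_matching_df(self):
        df = simulate_joint(6_000, 8, rr10=1.5, rr01=1.5)
        df["risk3"] = np.random.default_rng(0).choice(
            ["low", "intermediate", "high"], len(df)
        )
        out = multiplicative_lrt(df, "expo", "risk3")
        assert out["df"] == 2
        assert 0.0 <= out["p"] <= 1.0
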