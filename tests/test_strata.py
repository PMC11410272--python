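"""Age-window and sex-stratified effects and their difference tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsbench import (
    AnalysisFrame,
    age_group_difference,
    age_window_hr,
    sex_difference_test,
    sex_stratified_effect,
)
from prsbench.errors import EstimationError, GatedError
from prsbench.metrics import EffectEstimate
from prsbench.simulate import DiseaseSpec, MortalitySpec, SimulationConfig, simulate_cohort
from prsbench.cohort import align
from prsbench.strata import StratumEffect, significance_stars


def _stratum(log_effect, se, metric="hr_per_sd", label="x"):
    return StratumEffect(
        stratum=label,
        effect=EffectEstimate(
            metric=metric, estimate=float(np.exp(log_effect)) if metric != "beta_per_sd" else log_effect,
            se=se, ci_low=0, ci_high=10, n_total=1000, n_cases=100,
        ),
    )


class TestDifferenceArithmetic:
    def test_equal_effects_give_p_one(self):
        d = age_group_difference(_stratum(0.3, 0.1), _stratum(0.3, 0.1))
        assert d.difference == pytest.approx(0.0, abs=1e-12)
        assert d.p_value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        d = age_group_difference(_stratum(0.5, 0.1), _stratum(0.2, 0.1))
        assert d.difference == pytest.approx(0.3, abs=1e-12)
        assert d.se == pytest.approx(np.sqrt(0.02), abs=1e-12)
        assert d.z == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-6)  # ~2.12

    def test_antisymmetry(self):
        d1 = age_group_difference(_stratum(0.5, 0.1), _stratum(0.2, 0.15))
        d2 = age_group_difference(_stratum(0.2, 0.15), _stratum(0.5, 0.1))
        assert d1.difference == pytest.approx(-d2.difference)
        assert d1.p_value == pytest.approx(d2.p_value)

    def test_sex_difference_normal_cdf_oracle(self):
        f = _stratum(0.6, 0.05, metric="or_per_sd", label="female")
        m = _stratum(0.4, 0.05, metric="or_per_sd", label="male")
        d = sex_difference_test(f, m)
        z = 0.2 / np.sqrt(2 * 0.05**2)
        assert d.z == pytest.approx(z, abs=1e-9)           # ~2.83
        assert d.p_value == pytest.approx(2 * stats.norm.sf(z))  # ~0.0047
        assert d.stars == "**"

    def test_gated_stratum_undefined(self):
        g = _stratum(0.3, 0.1)
        g.effect.suppressed = True
        with pytest.raises(GatedError):
            age_group_difference(g, _stratum(0.2, 0.1))

    def test_stars_mapping(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.06) == ""


@pytest.fixture(scope="module")
def age_effect_sim():
    """Cohort whose PRS log-HR declines with age: 0.4 at age 40 falling by
    0.01/year (so ~0.2 at age 60)."""
    cfg = SimulationConfig(
        seed=31,
        n_per_ancestry={"EUR": 40000},
        diseases={
            "D": DiseaseSpec(
                name="D", log_hr_per_sd=0.4 + 0.01 * 40, age_slope=-0.01,
                sex_log_hr=0.0,
            )
        },
        quants={},
        score_correlation={},
        mortality=MortalitySpec(log_hr_per_sd={}),
    )
    # log_hr_per_sd is the effect at age 0; with slope -0.01 the effect at
    # age a is log_hr_per_sd - 0.01 a: 0.4 at 40, 0.2 at 60.
    sim = simulate_cohort(cfg)
    return align(sim.cohort, sim.scores, sim.diseases["D"])


class TestAgeWindow:
    def test_zero_horizon_is_gated(self, age_effect_sim):
        with pytest.raises((GatedError, EstimationError)):
            age_window_hr(age_effect_sim, (40, 49), horizon_years=0.0)

    def test_age_dependent_effect_recovered(self, age_effect_sim):
        young = age_window_hr(age_effect_sim, (40, 49), horizon_years=10)
        old = age_window_hr(age_effect_sim, (60, 69), horizon_years=10)
        d = age_group_difference(young, old)
        assert d.difference > 0
        assert d.p_value < 0.05
        # the Cox estimand under a time-varying effect is roughly the
        # event-weighted average of the generative log-HR 0.8 - 0.01*age
        df = age_effect_sim.data
        gen = {}
        for lo, hi in ((40, 49), (60, 69)):
            sel = (
                df["age_at_assessment"].between(lo, hi)
                & (df["case_flag"] == 1)
                & (df["event_age"] > df["age_at_assessment"])
                & (df["event_age"] <= df["age_at_assessment"] + 10)
            )
            gen[(lo, hi)] = float((0.8 - 0.01 * df.loc[sel, "event_age"]).mean())
        gen_diff = gen[(40, 49)] - gen[(60, 69)]
        assert d.ci_low - 0.05 < gen_diff < d.ci_high + 0.05

    def test_age_invariant_effect_near_zero_difference(self):
        cfg = SimulationConfig(
            seed=33, n_per_ancestry={"EUR": 30000},
            diseases={"D": DiseaseSpec(name="D", log_hr_per_sd=0.3, sex_log_hr=0.0)},
            quants={}, score_correlation={},
            mortality=MortalitySpec(log_hr_per_sd={}),
        )
        sim = simulate_cohort(cfg)
        frame = align(sim.cohort, sim.scores, sim.diseases["D"])
        young = age_window_hr(frame, (40, 49), horizon_years=10)
        old = age_window_hr(frame, (60, 69), horizon_years=10)
        d = age_group_difference(young, old)
        assert d.ci_low < 0 < d.ci_high

    def test_prevalent_cases_excluded(self, age_effect_sim):
        eff = age_window_hr(age_effect_sim, (55, 65), horizon_years=10)
        df = age_effect_sim.data
        sel = df["age_at_assessment"].between(55, 65)
        prevalent = (
            sel & (df["case_flag"] == 1) & (df["event_age"] <= df["age_at_assessment"])
        ).sum()
        assert eff.effect.n_total <= int(sel.sum()) - int(prevalent)


@pytest.fixture(scope="module")
def sexed_quant_sim():
    from prsbench.simulate import QuantSpec

    cfg = SimulationConfig(
        seed=37, n_per_ancestry={"EUR": 20000},
        diseases={}, score_correlation={},
        quants={"Q": QuantSpec(name="Q", beta_per_sd=0.3, sex_shift=0.0)},
        mortality=MortalitySpec(log_hr_per_sd={}),
    )
    sim = simulate_cohort(cfg)
    return sim, align(sim.cohort, sim.scores, sim.quants["Q"])


class TestSexStrata:
    def test_shared_effect_agrees_between_sexes(self, sexed_quant_sim):
        _, frame = sexed_quant_sim
        f = sex_stratified_effect(frame, "female", metric="beta_per_sd")
        m = sex_stratified_effect(frame, "male", metric="beta_per_sd")
        d = sex_difference_test(f, m)
        assert d.p_value > 0.01

    def test_male_shift_removed_by_within_sex_standardisation(self, sexed_quant_sim):
        _, frame = sexed_quant_sim
        base_all = sex_stratified_effect(frame, None, metric="beta_per_sd")
        shifted = frame.subset(np.ones(frame.n, dtype=bool))
        shifted.data = shifted.data.copy()
        shifted.data.loc[shifted.data["sex"] == "male", "value"] += 5.0
        shifted_all = sex_stratified_effect(shifted, None, metric="beta_per_sd")
        assert shifted_all.effect.estimate == pytest.approx(
            base_all.effect.estimate, abs=1e-10
        )

    def test_strata_partition_the_sample(self, sexed_quant_sim):
        _, frame = sexed_quant_sim
        f = sex_stratified_effect(frame, "female", metric="beta_per_sd")
        m = sex_stratified_effect(frame, "male", metric="beta_per_sd")
        a = sex_stratified_effect(frame, None, metric="beta_per_sd")
        assert f.effect.n_total + m.effect.n_total == a.effect.n_total

    def test_wrong_sex_for_restricted_trait_errors(self, sexed_quant_sim):
        _, frame = sexed_quant_sim
        frame2 = frame.subset((frame.data["sex"] == "female").to_numpy())
        frame2.sex_restriction = "female"
        with pytest.raises(EstimationError):
            sex_stratified_effect(frame2, "male", metric="beta_per_sd")

    def test_type_i_error_calibration_of_sex_difference(self):
        """Under a sex-homogeneous effect, the difference test rejects at
        ~5%: binomial check over 200 simulated replicates."""
        rng = np.random.default_rng(41)
        rejections = 0
        n = 600
        for _ in range(200):
            x = rng.normal(size=n)
            sex = np.where(rng.uniform(size=n) < 0.5, "female", "male")
            yv = 0.3 * x + rng.normal(scale=0.95, size=n)
            df = pd.DataFrame(
                {
                    "individual_id": [f"I{i}" for i in range(n)],
                    "sex": sex,
                    "age_at_assessment": 50.0,
                    "ancestry": "EUR",
                    "censor_age": 70.0,
                    "s": x,
                    "value": yv,
                }
            )
            frame = AnalysisFrame(data=df, trait_code="Q", kind="quant")
            f = sex_stratified_effect(frame, "female", metric="beta_per_sd")
            m = sex_stratified_effect(frame, "male", metric="beta_per_sd")
            if sex_difference_test(f, m).p_value < 0.05:
                rejections += 1
        # Binomial(200, 0.05): central 99.9% range ~ [1, 21]
        assert 1 <= rejections <= 21
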