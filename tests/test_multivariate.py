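"""Correlation structure, stepwise mortality models, C and R^2_D."""

import numpy as np
import pandas as pd
import pytest

from prsbench import (
    ScoreSet,
    cluster_order,
    harrells_c,
    harrells_c_difference,
    parent_offspring_ratio,
    prs_correlation_matrix,
    royston_r2,
    stepwise_mortality,
)
from prsbench.errors import EstimationError
from prsbench.multivariate import MortalityModel
from prsbench.simulate import MortalitySpec, QuantSpec, SimulationConfig, simulate_cohort


def _scores(n=1000, seed=0, names=("a", "b", "c"), corr=None):
    rng = np.random.default_rng(seed)
    k = len(names)
    C = np.eye(k) if corr is None else corr
    X = rng.normal(size=(n, k)) @ np.linalg.cholesky(C).T
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "individual_id", [f"I{i}" for i in range(n)])
    return ScoreSet(data=df)


class TestCorrelationMatrix:
    def test_diagonal_and_negation(self):
        ss = _scores(200, seed=1, names=("a", "b"))
        ss.data["b"] = -ss.data["a"]
        cm = prs_correlation_matrix(ss)
        f = cm.to_frame()
        assert f.loc["a", "a"] == 1.0
        assert f.loc["a", "b"] == pytest.approx(-1.0)

    def test_exact_symmetry_as_stored(self):
        cm = prs_correlation_matrix(_scores(500, seed=2))
        assert (cm.values == cm.values.T).all()

    def test_independent_scores_near_zero(self):
        cm = prs_correlation_matrix(_scores(10_000, seed=3, names=("a", "b")))
        assert abs(cm.to_frame().loc["a", "b"]) < 0.05

    def test_constant_column_flagged(self):
        ss = _scores(100, seed=4, names=("a", "b"))
        ss.data["b"] = 1.0
        cm = prs_correlation_matrix(ss)
        assert cm.undefined == ["b"]
        assert np.isnan(cm.to_frame().loc["a", "b"])
        with pytest.raises(EstimationError):
            cluster_order(cm)


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        ss = _scores(300, seed=5, names=("a", "b", "c", "d"))
        ss.data["d"] = ss.data["a"] + 1e-9 * np.arange(300)
        order = cluster_order(prs_correlation_matrix(ss))
        assert abs(order.index("a") - order.index("d")) == 1

    def test_hand_linkage_oracle(self):
        # build three scores with d(A,B) << d(A,C) = d(B,C): {A,B} merge first
        rng = np.random.default_rng(6)
        base = rng.normal(size=2000)
        other = rng.normal(size=2000)
        ss = ScoreSet(
            data=pd.DataFrame(
                {
                    "individual_id": [f"I{i}" for i in range(2000)],
                    "A": base + 0.1 * rng.normal(size=2000),
                    "B": base + 0.1 * rng.normal(size=2000),
                    "C": other,
                }
            )
        )
        order = cluster_order(prs_correlation_matrix(ss))
        assert abs(order.index("A") - order.index("B")) == 1
        assert order.index("C") in (0, 2)

    def test_invariant_to_input_permutation(self):
        ss = _scores(400, seed=7, names=("x", "y", "z", "w"))
        o1 = cluster_order(prs_correlation_matrix(ss))
        shuffled = ScoreSet(data=ss.data[["individual_id", "w", "y", "x", "z"]])
        o2 = cluster_order(prs_correlation_matrix(shuffled))
        assert o1 == o2


class TestHarrellsC:
    def test_perfect_ranking_is_one(self):
        # higher risk prediction -> earlier event
        assert harrells_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_four_subject_pair_enumeration_oracle(self):
        # predictions (4,3,1,2) vs times (1,2,3,4): one discordant pair of six
        assert harrells_c([4, 3, 1, 2], [1, 2, 3, 4], [1, 1, 1, 1]) == pytest.approx(5 / 6)

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(8)
        c = harrells_c(rng.normal(size=2000), rng.uniform(1, 10, 2000), np.ones(2000))
        assert c == pytest.approx(0.5, abs=0.03)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        p = rng.normal(size=300)
        t = rng.uniform(1, 5, 300)
        e = rng.integers(0, 2, 300)
        e[0] = 1
        assert harrells_c(p, t, e) == harrells_c(np.exp(2 * p), t, e)

    def test_no_events_errors(self):
        with pytest.raises(EstimationError):
            harrells_c([1, 2], [3, 4], [0, 0])

    def test_difference_bootstrap_ci_covers_delta(self):
        rng = np.random.default_rng(10)
        n = 800
        x = rng.normal(size=n)
        t = -np.log(rng.uniform(size=n)) / (0.1 * np.exp(0.8 * x))
        e = np.ones(n, dtype=int)
        res = harrells_c_difference(x, np.zeros(n) + rng.normal(scale=1e-9, size=n), t, e,
                                    n_bootstrap=200, seed=11)
        assert res["ci_low"] <= res["delta"] <= res["ci_high"]
        assert res["delta"] > 0
        assert res["p_value"] < 0.05


class TestRoystonR2:
    def test_constant_index_is_zero(self):
        assert royston_r2(np.ones(50), np.arange(1, 51.0), np.ones(50)) == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(12)
        n = 500
        x = rng.normal(size=n)
        t = -np.log(rng.uniform(size=n)) / (0.1 * np.exp(0.5 * x))
        r2 = royston_r2(x, t, np.ones(n))
        assert 0 <= r2 < 1

    def test_strong_predictor_beats_weak(self):
        rng = np.random.default_rng(13)
        n = 3000
        x = rng.normal(size=n)
        t = -np.log(rng.uniform(size=n)) / (0.1 * np.exp(1.0 * x))
        e = np.ones(n)
        strong = royston_r2(x, t, e)
        weak = royston_r2(x + 3 * rng.normal(size=n), t, e)
        assert strong > weak


@pytest.fixture(scope="module")
def mortality_sim():
    """One truly mortality-associated PRS among several null scores."""
    cfg = SimulationConfig(
        seed=51,
        n_per_ancestry={"EUR": 50000},
        diseases={},
        quants={f"q{i}": QuantSpec(name=f"q{i}", beta_per_sd=0.0) for i in range(5)},
        score_correlation={},
        mortality=MortalitySpec(log_hr_per_sd={"q0": 0.25}),
        followup_years=(12.0, 16.0),
    )
    return cfg, simulate_cohort(cfg)


class TestStepwise:
    def test_entry_p_zero_always_empty(self, mortality_sim):
        cfg, sim = mortality_sim
        model = stepwise_mortality(sim.cohort, sim.scores, target="own", entry_p=0.0)
        assert model.selected == []

    def test_selects_true_score_among_nulls(self, mortality_sim):
        cfg, sim = mortality_sim
        model = stepwise_mortality(sim.cohort, sim.scores, target="own", entry_p=1e-3)
        assert model.selected == ["q0"]
        lo, hi = model.ci["q0"]
        assert lo < 0.25 < hi

    def test_all_null_usually_empty(self):
        cfg = SimulationConfig(
            seed=53, n_per_ancestry={"EUR": 20000}, diseases={},
            quants={f"n{i}": QuantSpec(name=f"n{i}", beta_per_sd=0.0) for i in range(4)},
            score_correlation={},
            mortality=MortalitySpec(log_hr_per_sd={}),
        )
        sim = simulate_cohort(cfg)
        model = stepwise_mortality(sim.cohort, sim.scores, target="own", entry_p=1e-3)
        assert model.selected == []

    def test_parental_model_and_ratio(self, mortality_sim):
        cfg, sim = mortality_sim
        own = stepwise_mortality(sim.cohort, sim.scores, target="own", entry_p=1e-3)
        par = stepwise_mortality(sim.cohort, sim.scores, target="parental", entry_p=1e-2)
        assert "q0" in par.selected
        res = parent_offspring_ratio(own, par, "q0")
        assert res["ci_low"] < 2.0 < res["ci_high"]

    def test_parental_frame_has_two_rows_per_individual(self, mortality_sim):
        cfg, sim = mortality_sim
        assert len(sim.cohort.parents) == 2 * len(sim.cohort.data)


class TestRatioArithmetic:
    def _model(self, log_hr, se, target):
        return MortalityModel(
            target=target, selected=["s"], log_hr={"s": log_hr}, se={"s": se},
            ci={"s": (log_hr - 1.96 * se, log_hr + 1.96 * se)},
            baseline_covariates=[], n=1000, n_events=100,
            entry_p=1e-3, removal_p=1e-3,
        )

    def test_equal_log_hrs_ratio_one(self):
        r = parent_offspring_ratio(self._model(0.1, 0.01, "own"),
                                   self._model(0.1, 0.01, "parental"), "s")
        assert r["ratio"] == pytest.approx(1.0)

    def test_two_to_one(self):
        r = parent_offspring_ratio(self._model(0.10, 0.01, "own"),
                                   self._model(0.05, 0.01, "parental"), "s")
        assert r["ratio"] == pytest.approx(2.0)

    def test_missing_score_errors(self):
        with pytest.raises(EstimationError):
            parent_offspring_ratio(self._model(0.1, 0.01, "own"),
                                   MortalityModel("parental", [], {}, {}, {}, [], 0, 0, 1e-3, 1e-3),
                                   "s")
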