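"""Per-SD effect metrics against independent oracles.

Frozen oracle values were computed by direct maximisation of the written
likelihoods (iterated grid search refined to < 1e-9), independent of the
fitting code under test.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from prsbench import (
    AnalysisFrame,
    auc,
    beta_per_sd,
    effective_sample_size_cc,
    effective_sample_size_meta,
    hr_per_sd,
    or_per_sd,
    standardize_prs,
)
from prsbench._cox import coxph_fit
from prsbench.errors import DegenerateScoreError, EstimationError, SeparationError

# grid-search maximiser of the Bernoulli log-likelihood for
# x = (-1.2, -0.5, 0, 0.4, 0.9, 1.6), y = (0, 0, 1, 0, 1, 1), with intercept
LOGISTIC_ORACLE_SLOPE = 2.6702238929
# maximiser of the Breslow partial likelihood for times (2, 3, 5, 7),
# all events, x = (1, 0, 1, 0):  l(b) = 2b - log(2e^b+2) - log(e^b+2) - log(e^b+1)
COX_ORACLE_BETA = 0.9406136421


def _binary_frame(x, y, sex=None, age=None, censor=75.0):
    n = len(x)
    df = pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "sex": sex if sex is not None else ["female"] * n,
            "age_at_assessment": age if age is not None else [50.0] * n,
            "ancestry": ["EUR"] * n,
            "censor_age": [censor] * n,
            "s": np.asarray(x, dtype=float),
            "case_flag": np.asarray(y, dtype=int),
        }
    )
    df["event_age"] = np.where(df["case_flag"] == 1, 60.0, np.nan)
    return AnalysisFrame(data=df, trait_code="X", kind="binary")


class TestStandardize:
    def test_forced_affine_map(self):
        out = standardize_prs(np.array([0.0, 2.0]))
        assert out == pytest.approx([-1.0, 1.0])

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(size=100)
        z = standardize_prs(x)
        assert standardize_prs(z) == pytest.approx(z, abs=1e-12)

    def test_reference_subgroup_map_applied_globally(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(2, 3, 500)])
        ref = np.arange(1000) < 500
        z = standardize_prs(x, reference_mask=ref)
        assert np.std(z[ref]) == pytest.approx(1.0)
        assert np.mean(z[ref]) == pytest.approx(0.0, abs=1e-12)
        # other subgroup keeps its own (different) spread
        assert np.std(z[~ref]) == pytest.approx(3 / np.std(x[ref]), rel=0.2)
        assert abs(np.std(z[~ref]) - 1) > 0.5

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateScoreError):
            standardize_prs(np.ones(10))


class TestOrPerSd:
    def test_micro_dataset_matches_grid_search_mle(self):
        x = np.array([-1.2, -0.5, 0, 0.4, 0.9, 1.6])
        y = np.array([0, 0, 1, 0, 1, 1])
        frame = _binary_frame(x, y)
        # no covariates; undo the per-SD standardisation to compare with the
        # oracle computed on the raw x scale
        est = or_per_sd(frame, "s", covariates=())
        sd = np.std(x)
        assert np.log(est.estimate) / sd == pytest.approx(LOGISTIC_ORACLE_SLOPE, abs=1e-6)

    def test_null_is_near_one(self):
        rng = np.random.default_rng(4)
        n = 4000
        frame = _binary_frame(rng.normal(size=n), rng.integers(0, 2, size=n))
        est = or_per_sd(frame, "s", covariates=())
        assert est.ci_low < 1 < est.ci_high

    def test_separation_raises(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            or_per_sd(_binary_frame(x, y), "s", covariates=())

    def test_gate_suppresses_but_keeps_counts(self):
        rng = np.random.default_rng(5)
        frame = _binary_frame(rng.normal(size=200), rng.integers(0, 2, size=200))
        est = or_per_sd(frame, "s", covariates=(), min_cases=1000)
        assert est.suppressed and est.estimate is None
        assert est.n_cases > 0 and "1000" in est.gate_reason

    def test_scale_invariance_of_per_sd_estimate(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(int)
        e1 = or_per_sd(_binary_frame(x, y), "s", covariates=())
        e2 = or_per_sd(_binary_frame(7.3 * x, y), "s", covariates=())
        assert e1.estimate == pytest.approx(e2.estimate, abs=1e-10)


class TestHrPerSd:
    def test_micro_dataset_matches_enumerated_partial_likelihood(self):
        fit = coxph_fit(np.array([[1.0], [0.0], [1.0], [0.0]]), [2, 3, 5, 7], [1, 1, 1, 1])
        assert fit.params[0] == pytest.approx(COX_ORACLE_BETA, abs=1e-6)

    def test_agrees_with_statsmodels_breslow_with_ties(self):
        rng = np.random.default_rng(7)
        n = 1500
        x = rng.normal(size=(n, 2))
        tt = np.ceil(-np.log(rng.uniform(size=n)) / (0.1 * np.exp(0.3 * x[:, 0])))
        cc = np.ceil(rng.uniform(1, 15, size=n))
        dur = np.minimum(tt, cc)
        ev = (tt <= cc).astype(int)
        mine = coxph_fit(x, dur, ev)
        ref = sm.PHReg(dur, x, status=ev, ties="breslow").fit()
        assert mine.params == pytest.approx(ref.params, abs=1e-6)
        assert mine.se == pytest.approx(ref.bse, abs=1e-6)

    def test_left_truncation_agrees_with_statsmodels_entry(self):
        rng = np.random.default_rng(8)
        n = 1000
        x = rng.normal(size=(n, 1))
        tt = -np.log(rng.uniform(size=n)) / (0.05 * np.exp(0.4 * x[:, 0]))
        ent = rng.uniform(0, 3, size=n)
        cc = ent + rng.uniform(5, 30, size=n)
        dur = np.minimum(tt + ent, cc)
        ev = (tt + ent <= cc).astype(int)
        mine = coxph_fit(x, dur, ev, entries=ent)
        ref = sm.PHReg(dur, x, status=ev, entry=ent, ties="breslow").fit()
        assert mine.params == pytest.approx(ref.params, abs=1e-6)

    def test_constant_score_errors(self):
        frame = _binary_frame(np.ones(50), [1] * 25 + [0] * 25)
        with pytest.raises((DegenerateScoreError, EstimationError)):
            hr_per_sd(frame, "s", covariates=())

    def test_all_censored_errors(self):
        with pytest.raises(EstimationError):
            coxph_fit(np.array([[1.0], [0.0]]), [2, 3], [0, 0])


class TestBetaPerSd:
    def _quant_frame(self, x, y, sex=None):
        n = len(x)
        df = pd.DataFrame(
            {
                "individual_id": [f"I{i}" for i in range(n)],
                "sex": sex if sex is not None else ["female"] * n,
                "age_at_assessment": [50.0] * n,
                "ancestry": ["EUR"] * n,
                "censor_age": [70.0] * n,
                "s": np.asarray(x, dtype=float),
                "value": np.asarray(y, dtype=float),
            }
        )
        return AnalysisFrame(data=df, trait_code="Q", kind="quant")

    def test_trait_equal_to_prs_gives_unit_beta_and_r2(self):
        x = np.random.default_rng(9).normal(size=500)
        est = beta_per_sd(self._quant_frame(x, x), "s", covariates=())
        assert est.estimate == pytest.approx(1.0, abs=1e-10)
        assert est.extra["r2_incremental"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_trait_gives_null(self):
        rng = np.random.default_rng(10)
        est = beta_per_sd(
            self._quant_frame(rng.normal(size=5000), rng.normal(size=5000)),
            "s", covariates=(),
        )
        assert est.ci_low < 0 < est.ci_high
        assert est.extra["r2_incremental"] < 0.01

    def test_generative_truth_recovery(self):
        rng = np.random.default_rng(11)
        n = 100_000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(scale=0.954, size=n)
        est = beta_per_sd(self._quant_frame(x, y), "s", covariates=())
        assert est.estimate == pytest.approx(0.3, abs=0.01)
        assert est.extra["r2_incremental"] == pytest.approx(0.09, abs=0.005)

    def test_constant_trait_errors(self):
        with pytest.raises(DegenerateScoreError):
            beta_per_sd(self._quant_frame(np.arange(10.0), np.ones(10)), "s", covariates=())


class TestAuc:
    def test_printed_four_score_example(self):
        # cases {3, 2}, controls {1, 2}: 3 wins + 1 tie of 4 pairs = 0.875
        frame = _binary_frame([3.0, 2.0, 1.0, 2.0], [1, 1, 0, 0])
        est = auc(frame, "s")
        assert est.estimate == pytest.approx(0.875)

    def test_perfect_separation_is_one(self):
        frame = _binary_frame([5.0, 4.0, 1.0, 0.0], [1, 1, 0, 0])
        assert auc(frame, "s").estimate == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(12)
        n = 20000
        frame = _binary_frame(rng.normal(size=n), rng.integers(0, 2, size=n))
        assert auc(frame, "s").estimate == pytest.approx(0.5, abs=0.02)

    def test_exhaustive_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=60).round(1)  # induce ties
        y = rng.integers(0, 2, size=60)
        if y.sum() in (0, 60):
            y[0] = 1 - y[0]
        est = auc(_binary_frame(x, y), "s")
        cases, controls = x[y == 1], x[y == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        assert est.estimate == pytest.approx(wins / (len(cases) * len(controls)))

    def test_delong_se_against_bootstrap(self):
        rng = np.random.default_rng(14)
        n = 1500
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        est = auc(_binary_frame(x, y), "s")
        boots = []
        for _ in range(400):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if yb.sum() in (0, n):
                continue
            r = pd.Series(xb).rank()
            m = yb.sum()
            boots.append((r[yb == 1].sum() - m * (m + 1) / 2) / (m * (n - m)))
        assert est.se == pytest.approx(np.std(boots, ddof=1), rel=0.2)

    def test_no_cases_errors(self):
        with pytest.raises(EstimationError):
            auc(_binary_frame([1.0, 2.0], [0, 0]), "s")


class TestEffectiveSampleSize:
    def test_meta_examples(self):
        assert effective_sample_size_meta([(1000, 0.5)]) == pytest.approx(1000)
        assert effective_sample_size_meta([(1000, 0.1), (2000, 0.25)]) == pytest.approx(
            4 * (1000 * 0.09 + 2000 * 0.1875)
        )
        assert effective_sample_size_meta([]) == 0.0

    def test_cc_examples_and_limit(self):
        assert effective_sample_size_cc(500, 500) == pytest.approx(1000)
        assert effective_sample_size_cc(1000, 1000) == pytest.approx(2000)
        assert effective_sample_size_cc(10**9, 106) == pytest.approx(4 * 106, rel=1e-3)

    def test_identity_between_formulas(self):
        for n0, n1 in [(500, 500), (120, 37), (9999, 1)]:
            n = n0 + n1
            c = n1 / n
            assert effective_sample_size_cc(n0, n1) == pytest.approx(
                effective_sample_size_meta([(n, c)]), abs=1e-9
            )

    def test_invalid_inputs_error(self):
        with pytest.raises(EstimationError):
            effective_sample_size_meta([(100, 0.0)])
        with pytest.raises(EstimationError):
            effective_sample_size_cc(0, 10)
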