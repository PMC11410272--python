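"""Per-SD effect-size metrics, AUC, and effective-sample-size formulas.

Every disease metric is reported per standard deviation of the PRS after
standardisation within a reference subgroup (by default the ancestry group
being analysed), so odds/hazard ratios from different scores and different
groups are on a comparable scale:

* ``or_per_sd``   - logistic regression OR per SD, adjusting for age and sex
* ``hr_per_sd``   - Cox proportional-hazards HR per SD (age or follow-up
  timescale, optional left truncation at assessment)
* ``beta_per_sd`` - linear-regression effect on the standardised trait per
  SD, plus incremental r^2 over the covariate-only model
* ``auc``         - Mann-Whitney concordance of the PRS alone, DeLong CI

Effect estimates carry the case/total counts so that downstream gating
(>= 100 cases per ancestry group by default) can suppress the value while
keeping the accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._cox import coxph_fit
from .cohort import AnalysisFrame
from .errors import (
    ConvergenceError,
    DegenerateScoreError,
    EstimationError,
    SeparationError,
)

Z95 = stats.norm.ppf(0.975)


@dataclass
class EffectEstimate:
    """A performance metric with its uncertainty and sample accounting.

    For ratio metrics (``or_per_sd``, ``hr_per_sd``) the ``estimate`` is on
    the ratio scale and ``se`` is the standard error of the log estimate.
    ``suppressed`` marks a gated result: counts are present, the value is
    not to be reported.
    """

    metric: str
    estimate: float | None
    se: float | None
    ci_low: float | None
    ci_high: float | None
    n_total: int
    n_cases: int | None = None
    p_value: float | None = None
    stratum: dict = field(default_factory=dict)
    suppressed: bool = False
    gate_reason: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def log_estimate(self) -> float:
        if self.metric in ("or_per_sd", "hr_per_sd"):
            return float(np.log(self.estimate))
        return float(self.estimate)

    @property
    def log_se(self) -> float:
        return float(self.se)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_total": self.n_total,
            "n_cases": self.n_cases,
            "p_value": self.p_value,
            "stratum": self.stratum,
            "suppressed": self.suppressed,
            "gate_reason": self.gate_reason,
            **({"extra": self.extra} if self.extra else {}),
        }


def standardize_prs(
    scores: np.ndarray | pd.Series,
    reference_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Affine-map scores to mean 0 / SD 1 within the reference subgroup.

    The same map is applied to every individual, so subgroups other than
    the reference generally do not end up with unit SD.
    """
    x = np.asarray(scores, dtype=float)
    ref = x if reference_mask is None else x[np.asarray(reference_mask, dtype=bool)]
    if len(ref) < 2:
        raise DegenerateScoreError("reference subgroup needs at least 2 individuals")
    sd = np.std(ref)  # population SD: the map sends {0, 2} to {-1, +1}
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScoreError("score has zero variance in the reference subgroup")
    return (x - np.mean(ref)) / sd


def _design(frame: AnalysisFrame, score: str, covariates: Sequence[str]) -> tuple:
    """Build (standardized score, covariate matrix, usable-row frame).

    Rows with a missing score, covariate or outcome are dropped
    (complete-case); sex is coded female=0, male=1 and rows with missing
    sex are dropped whenever sex is a covariate.
    """
    df = frame.data
    cols = [score] + [c for c in covariates]
    keep = df[score].notna()
    for c in covariates:
        keep &= df[c].notna()
    df = df[keep]
    x = standardize_prs(df[score].to_numpy(dtype=float))
    covs = []
    for c in covariates:
        v = df[c]
        if c == "sex":
            covs.append((v == "male").to_numpy(dtype=float))
        else:
            covs.append(v.to_numpy(dtype=float))
    C = np.column_stack(covs) if covs else np.empty((len(df), 0))
    return x, C, df


def or_per_sd(
    frame: AnalysisFrame,
    score: str,
    covariates: Sequence[str] = ("age_at_assessment", "sex"),
    min_cases: int | None = None,
    stratum: dict | None = None,
) -> EffectEstimate:
    """Odds ratio per SD of PRS from logistic regression.

    Maximum-likelihood logistic coefficient of the standardized PRS,
    exponentiated, with a Wald 95% CI on the log scale.  Covariates default
    to age at assessment and sex; drop ``sex`` for sex-restricted traits.
    """
    if frame.kind != "binary":
        raise EstimationError("or_per_sd requires a binary phenotype")
    if frame.sex_restriction is not None:
        covariates = tuple(c for c in covariates if c != "sex")
    x, C, df = _design(frame, score, covariates)
    y = df["case_flag"].to_numpy(dtype=float)
    n_cases = int(y.sum())
    n = len(y)
    if n_cases == 0 or n_cases == n:
        raise EstimationError(f"need at least 1 case and 1 control, got {n_cases}/{n}")
    base = dict(metric="or_per_sd", n_total=n, n_cases=n_cases, stratum=stratum or {})
    if min_cases is not None and n_cases < min_cases:
        return EffectEstimate(
            estimate=None, se=None, ci_low=None, ci_high=None,
            suppressed=True, gate_reason=f"{n_cases} cases < {min_cases}", **base,
        )
    X = np.column_stack([np.ones(n), x, C])
    try:
        import warnings

        with np.errstate(over="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation diagnosed below
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if np.abs(res.params[1]) > 30 or not np.isfinite(res.bse[1]) or res.bse[1] > 100:
        raise SeparationError("complete separation: PRS coefficient diverged")
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic IRLS/Newton did not converge in 100 iterations")
    b, se = float(res.params[1]), float(res.bse[1])
    return EffectEstimate(
        estimate=float(np.exp(b)), se=se,
        ci_low=float(np.exp(b - Z95 * se)), ci_high=float(np.exp(b + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(b / se))), **base,
    )


def hr_per_sd(
    frame: AnalysisFrame,
    score: str,
    timescale: str = "age",
    covariates: Sequence[str] = ("age_at_assessment", "sex"),
    incident: bool = False,
    min_cases: int | None = None,
    stratum: dict | None = None,
) -> EffectEstimate:
    """Hazard ratio per SD of PRS from a Cox model (Breslow ties).

    ``timescale="age"`` uses age as the time axis (events at ``event_age``,
    censoring at ``censor_age``); with ``incident=True`` individuals enter
    the risk set at their assessment age (left truncation) and prevalent
    cases are excluded.  ``timescale="followup"`` measures time from
    assessment.  Age at assessment is dropped from the covariates on the
    age timescale, where it is the time axis itself.
    """
    if frame.kind != "binary":
        raise EstimationError("hr_per_sd requires a binary phenotype")
    if frame.sex_restriction is not None:
        covariates = tuple(c for c in covariates if c != "sex")
    if timescale == "age":
        covariates = tuple(c for c in covariates if c != "age_at_assessment")
    x, C, df = _design(frame, score, covariates)
    event = (df["case_flag"] == 1).to_numpy()
    event_age = df["event_age"].to_numpy(dtype=float)
    censor_age = df["censor_age"].to_numpy(dtype=float)
    assess = df["age_at_assessment"].to_numpy(dtype=float)
    times = np.where(event, event_age, censor_age)

    entries = None
    if timescale == "age":
        if incident:
            prevalent = event & (event_age <= assess)
            keep = ~prevalent & (times > assess)
            x, C, event, times, assess = x[keep], C[keep], event[keep], times[keep], assess[keep]
            entries = assess
        if np.any(times <= 0):
            raise EstimationError("non-positive event/censor ages on the age timescale")
    elif timescale == "followup":
        if incident:
            prevalent = event & (event_age <= assess)
            keep = ~prevalent
            x, C, event, times, assess = x[keep], C[keep], event[keep], times[keep], assess[keep]
        times = times - assess
        keep = times > 0
        x, C, event, times = x[keep], C[keep], event[keep], times[keep]
    else:
        raise EstimationError(f"unknown timescale {timescale!r}")

    n, n_events = len(times), int(event.sum())
    if n_events == 0:
        raise EstimationError("all individuals censored; no events to fit")
    base = dict(metric="hr_per_sd", n_total=n, n_cases=n_events, stratum=stratum or {})
    if min_cases is not None and n_events < min_cases:
        return EffectEstimate(
            estimate=None, se=None, ci_low=None, ci_high=None,
            suppressed=True, gate_reason=f"{n_events} events < {min_cases}", **base,
        )
    X = np.column_stack([x, C])
    fit = coxph_fit(X, times, event.astype(int), entries=entries)
    b, se = float(fit.params[0]), float(fit.se[0])
    return EffectEstimate(
        estimate=float(np.exp(b)), se=se,
        ci_low=float(np.exp(b - Z95 * se)), ci_high=float(np.exp(b + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(b / se))), **base,
    )


def beta_per_sd(
    frame: AnalysisFrame,
    score: str,
    covariates: Sequence[str] = ("age_at_assessment", "sex"),
    sex_standardize: bool = False,
    stratum: dict | None = None,
) -> EffectEstimate:
    """OLS effect of the PRS on the standardised quantitative trait.

    The trait is standardised to zero mean and unit variance — within each
    sex separately when ``sex_standardize`` (then pooled), otherwise in the
    whole analysis frame.  r^2 is reported as the increment in model R^2
    from adding the PRS to the covariate-only model.
    """
    if frame.kind != "quant":
        raise EstimationError("beta_per_sd requires a quantitative phenotype")
    if frame.sex_restriction is not None:
        covariates = tuple(c for c in covariates if c != "sex")
    if sex_standardize:
        covariates = tuple(c for c in covariates if c != "sex")
    x, C, df = _design(frame, score, covariates)
    y = df["value"].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DegenerateScoreError("quantitative trait is constant")
    if sex_standardize:
        sexes = df["sex"].to_numpy()
        y = y.copy()
        for s in np.unique(sexes):
            m = sexes == s
            sd = np.std(y[m])
            if sd == 0:
                raise DegenerateScoreError(f"trait constant within sex {s!r}")
            y[m] = (y[m] - np.mean(y[m])) / sd
    else:
        y = (y - np.mean(y)) / np.std(y)
    n = len(y)
    X_cov = np.column_stack([np.ones(n), C])
    X_full = np.column_stack([np.ones(n), x, C])
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_cov).fit()
    b, se = float(full.params[1]), float(full.bse[1])
    return EffectEstimate(
        metric="beta_per_sd", estimate=b, se=se,
        ci_low=b - Z95 * se, ci_high=b + Z95 * se,
        n_total=n, p_value=float(full.pvalues[1]), stratum=stratum or {},
        extra={"r2_incremental": float(full.rsquared - reduced.rsquared)},
    )


def _auc_delong(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC and its DeLong standard error."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    ranks = stats.rankdata(all_scores)  # midranks handle ties as 1/2
    r_cases = ranks[:m]
    auc_hat = (r_cases.sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (r_cases - stats.rankdata(cases)) / n
    v01 = 1 - (ranks[m:] - stats.rankdata(controls)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc_hat), float(np.sqrt(s10 / m + s01 / n))


def auc(
    frame: AnalysisFrame,
    score: str,
    min_cases: int | None = None,
    stratum: dict | None = None,
) -> EffectEstimate:
    """AUC of the PRS alone: the probability a random case outscores a
    random control, ties counted 1/2.  DeLong analytic 95% CI."""
    if frame.kind != "binary":
        raise EstimationError("auc requires a binary phenotype")
    df = frame.data[frame.data[score].notna()]
    y = df["case_flag"].to_numpy(dtype=int)
    s = df[score].to_numpy(dtype=float)
    cases, controls = s[y == 1], s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise EstimationError(
            f"AUC needs cases and controls, got {len(cases)}/{len(controls)}"
        )
    base = dict(metric="auc", n_total=len(s), n_cases=len(cases), stratum=stratum or {})
    if min_cases is not None and len(cases) < min_cases:
        return EffectEstimate(
            estimate=None, se=None, ci_low=None, ci_high=None,
            suppressed=True, gate_reason=f"{len(cases)} cases < {min_cases}", **base,
        )
    a, se = _auc_delong(cases, controls)
    return EffectEstimate(
        estimate=a, se=se,
        ci_low=max(0.0, a - Z95 * se), ci_high=min(1.0, a + Z95 * se), **base,
    )


def effective_sample_size_meta(components: Sequence[tuple[float, float]]) -> float:
    """GWAS-meta effective sample size: 4 * sum_j n_j c_j (1 - c_j)."""
    total = 0.0
    for n_j, c_j in components:
        if n_j <= 0:
            raise EstimationError(f"component size must be positive, got {n_j}")
        if not 0 < c_j < 1:
            raise EstimationError(f"case fraction must be in (0,1), got {c_j}")
        total += n_j * c_j * (1 - c_j)
    return 4 * total


def effective_sample_size_cc(n_controls: int, n_cases: int) -> float:
    """Case-control effective sample size: 4 / (1/n0 + 1/n1)."""
    if n_controls <= 0 or n_cases <= 0:
        raise EstimationError("both case and control counts must be positive")
    return 4 / (1 / n_controls + 1 / n_cases)
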