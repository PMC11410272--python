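"""Head-to-head PRS comparison and cross-ancestry relative performance.

``bootstrap_compare`` is the like-for-like test between two scores for the
same trait: individuals are resampled with replacement and *the same
resample indices are applied to both scores*, so the difference of the two
(log-scale) estimates per replicate reflects only the scores, not sampling
noise in who was drawn.  The two-tailed p-value is twice the smaller tail
fraction of the bootstrap difference distribution around zero, clipped
below at 2/(B+1).

``ancestry_relative_change`` expresses a non-European stratum's log-scale
effect relative to the European reference — e.g. -0.094 means the log-OR
per SD is 9.4% smaller — with a delta-method CI treating strata as
independent; ``average_relative_change`` pools per-trait changes by
inverse-variance fixed-effect weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cohort import AnalysisFrame
from .errors import EstimationError
from .metrics import EffectEstimate, Z95, auc, beta_per_sd, or_per_sd

#: metric name -> (estimator, uses log scale for the compared statistic)
_METRICS: dict[str, tuple[Callable, bool]] = {
    "or_per_sd": (or_per_sd, True),
    "beta_per_sd": (beta_per_sd, False),
    "auc": (auc, False),
}


@dataclass
class ComparisonResult:
    metric: str
    estimate_a: float
    estimate_b: float
    difference: float           # log scale for ratio metrics
    ci_low: float
    ci_high: float
    p_value: float
    n_bootstrap: int
    seed: int
    n: int
    scale: str = "log"
    n_failed: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class RelativeChange:
    reference: str
    target: str
    change: float               # fractional change of the log-scale effect
    se: float
    ci_low: float
    ci_high: float
    trait: str | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _stat(metric: str, frame: AnalysisFrame, score: str, **kw) -> float:
    fn, log_scale = _METRICS[metric]
    est = fn(frame, score, **kw)
    return est.log_estimate if log_scale else float(est.estimate)


def bootstrap_compare(
    frame: AnalysisFrame,
    score_a: str,
    score_b: str,
    metric: str = "or_per_sd",
    n_bootstrap: int = 5000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
    **metric_kw,
) -> ComparisonResult:
    """Paired-bootstrap comparison of two scores on the same individuals.

    Returns the observed difference (log scale for ratio metrics), the
    percentile 95% CI of the bootstrap differences, and the two-tailed
    bootstrap p-value.  Identical score columns short-circuit to
    difference 0, p = 1.
    """
    if metric not in _METRICS:
        raise EstimationError(f"unknown comparison metric {metric!r}")
    _, log_scale = _METRICS[metric]
    a_obs_est = _METRICS[metric][0](frame, score_a, **metric_kw)
    b_obs_est = _METRICS[metric][0](frame, score_b, **metric_kw)
    a_obs = a_obs_est.log_estimate if log_scale else float(a_obs_est.estimate)
    b_obs = b_obs_est.log_estimate if log_scale else float(b_obs_est.estimate)
    n = frame.n
    base = dict(
        metric=metric, estimate_a=float(a_obs_est.estimate),
        estimate_b=float(b_obs_est.estimate), n_bootstrap=n_bootstrap,
        seed=seed, n=n, scale="log" if log_scale else "natural",
    )
    sa = frame.data[score_a].to_numpy(dtype=float)
    sb = frame.data[score_b].to_numpy(dtype=float)
    if np.array_equal(sa, sb):
        return ComparisonResult(
            difference=0.0, ci_low=0.0, ci_high=0.0, p_value=1.0, **base
        )

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_bootstrap)
    n_failed = 0
    for b in range(n_bootstrap):
        # paired resample: same indices for both scores
        idx = rng.integers(0, n, size=n)
        resampled = frame.data.iloc[idx].reset_index(drop=True)
        sub = AnalysisFrame(
            data=resampled, trait_code=frame.trait_code, kind=frame.kind,
            dropped=frame.dropped, sex_restriction=frame.sex_restriction,
            age_window=frame.age_window,
        )
        try:
            diffs[b] = _stat(metric, sub, score_a, **metric_kw) - _stat(
                metric, sub, score_b, **metric_kw
            )
        except EstimationError:
            diffs[b] = np.nan
            n_failed += 1
    if n_failed > max_failure_rate * n_bootstrap:
        raise EstimationError(
            f"metric failed in {n_failed}/{n_bootstrap} bootstrap replicates"
        )
    diffs = diffs[~np.isnan(diffs)]
    observed = a_obs - b_obs
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    frac_le = np.mean(diffs <= 0)
    frac_ge = np.mean(diffs >= 0)
    p = 2 * min(frac_le, frac_ge)
    p = float(np.clip(p, 2 / (n_bootstrap + 1), 1.0))
    return ComparisonResult(
        difference=float(observed), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=p, n_failed=n_failed, **base,
    )


def ancestry_relative_change(
    estimate_target: EffectEstimate,
    estimate_ref: EffectEstimate,
    trait: str | None = None,
) -> RelativeChange:
    """Fractional change of the target stratum's log-scale effect relative
    to the reference: (log_t - log_r) / log_r (beta scale for quantitative
    metrics).  Delta-method 95% CI with independent strata."""
    for est in (estimate_target, estimate_ref):
        if est.suppressed:
            raise EstimationError("relative change undefined for gated estimates")
    a = estimate_ref.log_estimate     # reference log effect
    b = estimate_target.log_estimate
    va = estimate_ref.log_se ** 2
    vb = estimate_target.log_se ** 2
    if a <= 0:
        raise EstimationError(
            f"reference log-effect must be positive, got {a:.4g}"
        )
    change = (b - a) / a
    # f(a,b) = b/a - 1 ; var = (1/a^2) vb + (b^2/a^4) va
    var = vb / a**2 + (b**2 / a**4) * va
    se = float(np.sqrt(var))
    return RelativeChange(
        reference=str(estimate_ref.stratum.get("ancestry", "ref")),
        target=str(estimate_target.stratum.get("ancestry", "target")),
        change=float(change), se=se,
        ci_low=float(change - Z95 * se), ci_high=float(change + Z95 * se),
        trait=trait,
    )


def average_relative_change(changes: Sequence[RelativeChange]) -> RelativeChange:
    """Inverse-variance-weighted fixed-effect mean of per-trait relative
    changes, with its 95% CI."""
    changes = [c for c in changes if c is not None]
    if not changes:
        raise EstimationError("no defined relative changes to average")
    w = np.array([1 / c.se**2 for c in changes])
    x = np.array([c.change for c in changes])
    pooled = float((w * x).sum() / w.sum())
    se = float(np.sqrt(1 / w.sum()))
    return RelativeChange(
        reference=changes[0].reference,
        target=changes[0].target,
        change=pooled, se=se,
        ci_low=pooled - Z95 * se, ci_high=pooled + Z95 * se,
        trait="pooled",
    )


def gate(
    estimates: Sequence[EffectEstimate], min_cases: int = 100
) -> list[EffectEstimate]:
    """Suppress estimates whose case count is below ``min_cases`` ("at
    least" semantics: exactly min_cases is retained); counts stay."""
    out = []
    for est in estimates:
        n_cases = est.n_cases if est.n_cases is not None else est.n_total
        if n_cases < min_cases and not est.suppressed:
            est = EffectEstimate(
                metric=est.metric, estimate=None, se=None,
                ci_low=None, ci_high=None,
                n_total=est.n_total, n_cases=est.n_cases,
                stratum=est.stratum, suppressed=True,
                gate_reason=f"{n_cases} cases < {min_cases}",
            )
        out.append(est)
    return out


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Optional multiple-testing helper (off by default in the pipeline)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
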