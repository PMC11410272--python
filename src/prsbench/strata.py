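"""Age-window and sex-stratified PRS effects and their difference tests.

Age windows answer "does the PRS discriminate better in people assessed
young?": within an age-at-assessment band, prevalent cases are excluded
and the Cox log-HR per SD is estimated from incident events over the next
``horizon_years`` of follow-up.  Sex strata re-estimate each metric within
one sex (age adjustment only — sex is constant in the stratum), with
quantitative traits standardised within sex before any pooled analysis.
Differences between two disjoint strata are z-tests with independent SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import AnalysisFrame
from .errors import EstimationError, GatedError
from .metrics import EffectEstimate, Z95, auc, beta_per_sd, hr_per_sd, or_per_sd


@dataclass
class StratumEffect:
    stratum: str
    effect: EffectEstimate
    window: dict | None = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "effect": self.effect.to_dict(),
            "window": self.window,
        }


@dataclass
class DifferenceTest:
    difference: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    stars: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def age_window_hr(
    frame: AnalysisFrame,
    age_band: tuple[float, float],
    horizon_years: float = 10.0,
    covariates=("age_at_assessment", "sex"),
    min_cases: int | None = None,
) -> StratumEffect:
    """Cox log-HR per SD from incident events within ``horizon_years`` of
    assessment, for individuals assessed at ages in ``age_band``.

    Prevalent cases (diagnosed at or before assessment) are excluded;
    follow-up is censored at the horizon.
    """
    lo, hi = age_band
    df = frame.data
    sel = (df["age_at_assessment"] >= lo) & (df["age_at_assessment"] <= hi)
    sub = frame.subset(sel.to_numpy())
    if sub.n == 0:
        raise EstimationError(f"no individuals assessed at ages [{lo}, {hi}]")
    # censor at the horizon: cap event/censor ages at assessment + horizon
    capped = sub.data.copy()
    cap = capped["age_at_assessment"] + horizon_years
    beyond = capped["event_age"].notna() & (capped["event_age"] > cap)
    capped.loc[beyond, "case_flag"] = 0
    capped.loc[beyond, "event_age"] = np.nan
    capped["censor_age"] = np.minimum(capped["censor_age"], cap)
    sub = AnalysisFrame(
        data=capped, trait_code=sub.trait_code, kind=sub.kind,
        dropped=sub.dropped, sex_restriction=sub.sex_restriction,
        age_window=sub.age_window,
    )
    n_incident = int(
        (
            (capped["case_flag"] == 1)
            & (capped["event_age"] > capped["age_at_assessment"])
        ).sum()
    )
    if n_incident == 0:
        raise GatedError(
            f"no incident events within {horizon_years} years in band [{lo}, {hi}]"
        )
    eff = hr_per_sd(
        sub, score=_single_score(sub), timescale="followup", incident=True,
        covariates=covariates, min_cases=min_cases,
        stratum={"age_band": [lo, hi]},
    )
    return StratumEffect(
        stratum=f"assessed {lo:g}-{hi:g}",
        effect=eff,
        window={"age_band": [lo, hi], "horizon_years": horizon_years},
    )


def _single_score(frame: AnalysisFrame) -> str:
    known = {
        "individual_id", "sex", "age_at_assessment", "ancestry", "censor_age",
        "death_age", "case_flag", "event_age", "value", "treatment_flag",
        "carrier_flag",
    }
    scores = [c for c in frame.data.columns if c not in known]
    if len(scores) != 1:
        raise EstimationError(
            f"expected exactly one score column, found {scores}; pass score= explicitly"
        )
    return scores[0]


def _log_scale_diff(e1: EffectEstimate, e2: EffectEstimate) -> DifferenceTest:
    for e in (e1, e2):
        if e.suppressed:
            raise GatedError("difference undefined: a stratum estimate is gated")
    d = e1.log_estimate - e2.log_estimate
    se = float(np.sqrt(e1.log_se**2 + e2.log_se**2))
    z = d / se
    p = float(2 * stats.norm.sf(abs(z)))
    return DifferenceTest(
        difference=float(d), se=se,
        ci_low=float(d - Z95 * se), ci_high=float(d + Z95 * se),
        z=float(z), p_value=p, stars=significance_stars(p),
    )


def age_group_difference(
    effect_young: StratumEffect, effect_old: StratumEffect
) -> DifferenceTest:
    """Difference of log-HRs between two age-at-assessment bands, Wald CI
    and two-tailed p treating the bands as independent."""
    return _log_scale_diff(effect_young.effect, effect_old.effect)


def sex_stratified_effect(
    frame: AnalysisFrame,
    sex: str | None,
    metric: str = "or_per_sd",
    min_cases: int | None = None,
    score: str | None = None,
) -> StratumEffect:
    """Effect within one sex (or the pooled "all" analysis for sex=None).

    Disease metrics adjust for age only within a sex stratum.  For
    quantitative traits the trait is standardised to zero mean / unit SD
    within each sex separately — also for the pooled analysis, matching
    the convention that makes female and male effects comparable.
    """
    if frame.sex_restriction is not None and sex is not None:
        if sex != frame.sex_restriction:
            raise EstimationError(
                f"trait restricted to {frame.sex_restriction}; cannot stratify to {sex}"
            )
    if sex is None:
        sub = frame.subset(frame.data["sex"].notna().to_numpy())
        label = "all"
    else:
        sub = frame.subset((frame.data["sex"] == sex).to_numpy())
        label = sex
    if sub.n == 0:
        raise EstimationError(f"empty sex stratum {label!r}")
    if score is None:
        score = _single_score(sub)
    stratum = {"sex": label}
    if metric == "or_per_sd":
        eff = or_per_sd(
            sub, score, covariates=("age_at_assessment",),
            min_cases=min_cases, stratum=stratum,
        )
    elif metric == "hr_per_sd":
        eff = hr_per_sd(
            sub, score, covariates=("age_at_assessment",),
            min_cases=min_cases, stratum=stratum,
        )
    elif metric == "beta_per_sd":
        eff = beta_per_sd(
            sub, score, covariates=("age_at_assessment",),
            sex_standardize=True, stratum=stratum,
        )
    elif metric == "auc":
        eff = auc(sub, score, min_cases=min_cases, stratum=stratum)
    else:
        raise EstimationError(f"unknown metric {metric!r}")
    return StratumEffect(stratum=label, effect=eff)


def sex_difference_test(
    effect_f: StratumEffect, effect_m: StratumEffect
) -> DifferenceTest:
    """Two-tailed z-test for female-vs-male difference in effect size, on
    the log scale for ratio metrics; stars at 0.05/0.01/0.001."""
    return _log_scale_diff(effect_f.effect, effect_m.effect)
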