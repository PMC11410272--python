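"""PRS percentile bands and Kaplan-Meier cumulative incidence.

Band membership is by empirical percentile rank of the score within the
evaluation subgroup: individuals are ordered by (score, individual_id) —
the id breaks ties deterministically — ranked 1..n, and the percentile of
rank r is 100*r/n.  A band (low, high] holds the individuals with
low < percentile <= high, so with n = 100 distinct scores the (97, 100]
band is exactly the 3 largest.

Cumulative incidence is one minus the product-limit survival estimate on
the age axis, with Greenwood variance and log(-log) (exponential
Greenwood) pointwise 95% bounds, delegated to lifelines.  Death and loss
to follow-up are treated as censoring, not competing risks.  Two modes:

* ``lifetime`` (default): individuals are at risk from age 0 and all
  recorded diagnoses count, including those before study entry.
* ``incident``: risk starts at the assessment age (left truncation) and
  prevalent cases are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import AnalysisFrame
from .errors import EstimationError, GatedError, ValidationError


@dataclass(frozen=True)
class PercentileBand:
    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.low < self.high <= 100):
            raise ValidationError(f"band ({self.low}, {self.high}) invalid")
        if not self.label:
            object.__setattr__(self, "label", default_band_label(self.low, self.high))


def default_band_label(low: float, high: float) -> str:
    def fmt(x: float) -> str:
        return f"{x:g}"
    if high == 100:
        return f"top {fmt(100 - low)}%"
    if low == 0:
        return f"bottom {fmt(high)}%"
    return f"{fmt(low)}-{fmt(high)}%"


@dataclass
class IncidenceCurve:
    """A step-function cumulative-incidence estimate for one PRS band."""

    band: PercentileBand | None
    grid: np.ndarray            # ascending ages (event/censor times)
    cum_inc: np.ndarray         # nondecreasing, in [0, 1]
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: int
    n_members: int
    mode: str = "lifetime"
    suppressed: bool = False
    gate_reason: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.grid,
                "cum_inc": self.cum_inc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
            }
        )

    def to_dict(self) -> dict:
        d = {
            "band": None if self.band is None else
                {"low": self.band.low, "high": self.band.high, "label": self.band.label},
            "n_events": self.n_events,
            "n_members": self.n_members,
            "mode": self.mode,
            "suppressed": self.suppressed,
            "gate_reason": self.gate_reason,
        }
        if not self.suppressed:
            d["curve"] = {
                "age": self.grid.tolist(),
                "cum_inc": self.cum_inc.tolist(),
                "ci_low": self.ci_low.tolist(),
                "ci_high": self.ci_high.tolist(),
                "n_at_risk": self.n_at_risk.tolist(),
            }
        return d


def percentile_ranks(scores: pd.Series, ids: pd.Series | None = None) -> np.ndarray:
    """Empirical percentile of each score: 100 * rank / n, ranks 1..n
    assigned by sorting on (score, id) so ties resolve deterministically."""
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n == 0:
        raise EstimationError("empty score vector")
    tie_break = (
        np.asarray(ids).astype(str)
        if ids is not None
        else np.arange(n).astype(str)
    )
    order = np.lexsort((tie_break, s))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return 100.0 * ranks / n


def assign_bands(
    scores: pd.Series,
    bands: list[PercentileBand],
    ids: pd.Series | None = None,
) -> dict[str, np.ndarray]:
    """Membership masks per band label; each individual in at most one
    configured band (bands are validated non-overlapping upstream)."""
    pct = percentile_ranks(scores, ids)
    out: dict[str, np.ndarray] = {}
    for band in bands:
        mask = (pct > band.low) & (pct <= band.high)
        out[band.label] = mask
    return out


def km_curve(
    frame: AnalysisFrame,
    members: np.ndarray | None = None,
    mode: str = "lifetime",
    band: PercentileBand | None = None,
    min_cases_curve: int | None = 40,
) -> IncidenceCurve:
    """Kaplan-Meier cumulative incidence for one band membership.

    The curve is suppressed (not an error) when the band's event count is
    not above ``min_cases_curve`` — "more than 40 cases" by default; pass
    ``None`` to disable the gate.
    """
    if frame.kind != "binary":
        raise EstimationError("km_curve requires a binary phenotype")
    df = frame.data if members is None else frame.data[np.asarray(members, dtype=bool)]
    n_members = len(df)
    if n_members == 0:
        raise EstimationError("empty band membership")
    event = (df["case_flag"] == 1).to_numpy()
    times = np.where(
        event, df["event_age"].to_numpy(dtype=float), df["censor_age"].to_numpy(dtype=float)
    )
    entries = None
    if mode == "incident":
        assess = df["age_at_assessment"].to_numpy(dtype=float)
        prevalent = event & (df["event_age"].to_numpy(dtype=float) <= assess)
        keep = ~prevalent & (times > assess)
        times, event, assess = times[keep], event[keep], assess[keep]
        entries = assess
        n_members = int(keep.sum())
    elif mode != "lifetime":
        raise EstimationError(f"unknown incidence mode {mode!r}")
    if np.any(times <= 0):
        raise ValidationError("non-positive event/censoring ages")

    n_events = int(event.sum())
    if min_cases_curve is not None and not n_events > min_cases_curve:
        return IncidenceCurve(
            band=band, grid=np.array([]), cum_inc=np.array([]),
            ci_low=np.array([]), ci_high=np.array([]), n_at_risk=np.array([]),
            n_events=n_events, n_members=n_members, mode=mode,
            suppressed=True,
            gate_reason=f"{n_events} cases not > {min_cases_curve}",
        )

    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(times, event_observed=event.astype(int), entry=entries)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    grid = surv.index.to_numpy(dtype=float)
    cum_inc = 1.0 - surv.to_numpy(dtype=float)
    # survival upper bound -> incidence lower bound
    ci_low = 1.0 - ci.iloc[:, 1].to_numpy(dtype=float)
    ci_high = 1.0 - ci.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    if frame.age_window is not None:
        lo, hi = frame.age_window
        keep = (grid >= lo) & (grid <= hi)
        keep[0] = True  # always keep the curve origin
        grid, cum_inc = grid[keep], cum_inc[keep]
        ci_low, ci_high, at_risk = ci_low[keep], ci_high[keep], at_risk[keep]
    return IncidenceCurve(
        band=band, grid=grid, cum_inc=cum_inc, ci_low=ci_low, ci_high=ci_high,
        n_at_risk=at_risk, n_events=n_events, n_members=n_members, mode=mode,
    )


def risk_at_age(curve: IncidenceCurve, age: float) -> tuple[float, float, float]:
    """Evaluate the (right-continuous) incidence step function at ``age``.

    Below the first grid point the risk is 0; above the last, the final
    value is returned (the caller sees the curve's support via ``grid``).
    """
    if curve.suppressed:
        raise GatedError(f"curve suppressed: {curve.gate_reason}")
    idx = np.searchsorted(curve.grid, age, side="right") - 1
    if idx < 0:
        return 0.0, 0.0, 0.0
    return (
        float(curve.cum_inc[idx]),
        float(curve.ci_low[idx]),
        float(curve.ci_high[idx]),
    )
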