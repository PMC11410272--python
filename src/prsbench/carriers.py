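"""Rare-variant carrier risk versus PRS-stratum risk.

Carriers of rare pathogenic variants (e.g. familial hypercholesterolemia
genes for coronary artery disease) define a reference level of cumulative
risk.  ``match_percentile`` finds the top fraction q of the PRS
distribution whose Kaplan-Meier risk at an anchor age (70 by default)
comes closest to the carrier risk, searching a 0.5-percentile grid —
continuous root-finding is pointless because KM risk is a step function of
q.  ``case_ratio_by_age`` counts how many diagnosed cases before each age
cutoff fall in the matched high-PRS band versus among carriers, and
``prs_modulation_of_carriers`` stratifies the carriers themselves by their
PRS band (bands defined on the full-cohort distribution).

Subgroup filters such as "statin-free" are plain row predicates applied to
the analysis frame before any of this; the report records the filter
description alongside the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AnalysisFrame, CarrierTable
from .errors import EstimationError
from .incidence import IncidenceCurve, PercentileBand, km_curve, percentile_ranks, risk_at_age


@dataclass
class EquivalenceResult:
    carrier_risk: float
    carrier_ci: tuple[float, float]
    matched_fraction: float             # q in (0, 1)
    matched_band_risk: float
    matched_band_ci: tuple[float, float]
    anchor_age: float
    subgroup_filter: str = ""
    n_carriers: int = 0
    n_band: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["carrier_ci"] = list(self.carrier_ci)
        d["matched_band_ci"] = list(self.matched_band_ci)
        return d


@dataclass
class CaseRatioResult:
    cutoffs: list[float]
    band_cases: list[int]
    carrier_cases: list[int]
    ratios: list[float | None]
    top_fraction: float
    overlap_count: int = 0
    overlap_expected: float = 0.0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _merge_carriers(frame: AnalysisFrame, carriers: CarrierTable) -> pd.DataFrame:
    df = frame.data
    if "carrier_flag" in df.columns:
        return df
    return df.merge(
        carriers.data[["individual_id", "carrier_flag"]], on="individual_id", how="left"
    ).fillna({"carrier_flag": 0})


def carrier_cumulative_risk(
    frame: AnalysisFrame,
    carriers: CarrierTable,
    anchor_age: float = 70.0,
    mode: str = "lifetime",
    min_cases_curve: int | None = None,
) -> tuple[float, tuple[float, float], IncidenceCurve]:
    """KM cumulative incidence among carriers at the anchor age.

    The curve gate is off by default here: carrier groups are small by
    construction and the published carrier analyses report them anyway.
    """
    df = _merge_carriers(frame, carriers)
    mask = (df["carrier_flag"] == 1).to_numpy()
    if mask.sum() == 0:
        raise EstimationError("no carriers in the analysis frame")
    sub = AnalysisFrame(
        data=df[mask].reset_index(drop=True), trait_code=frame.trait_code,
        kind=frame.kind, dropped=frame.dropped,
        sex_restriction=frame.sex_restriction, age_window=frame.age_window,
    )
    if int((sub.data["case_flag"] == 1).sum()) == 0:
        raise EstimationError("no carrier cases; carrier risk undefined")
    curve = km_curve(sub, mode=mode, min_cases_curve=min_cases_curve)
    risk, lo, hi = risk_at_age(curve, anchor_age)
    return risk, (lo, hi), curve


def _top_band_risk(
    frame: AnalysisFrame,
    score: str,
    q: float,
    anchor_age: float,
    mode: str,
) -> tuple[float, tuple[float, float], int]:
    pct = percentile_ranks(frame.data[score], frame.data["individual_id"])
    mask = pct > 100 * (1 - q)
    if mask.sum() == 0:
        raise EstimationError(f"top fraction {q} selects no individuals")
    curve = km_curve(frame, mask, mode=mode, band=None, min_cases_curve=None)
    risk, lo, hi = risk_at_age(curve, anchor_age)
    return risk, (lo, hi), int(mask.sum())


def match_percentile(
    frame: AnalysisFrame,
    score: str,
    target_risk: float,
    anchor_age: float = 70.0,
    search_bounds: tuple[float, float] = (0.001, 0.5),
    grid_step: float = 0.005,
    mode: str = "lifetime",
    subgroup_filter: str = "",
    carrier_ci: tuple[float, float] = (np.nan, np.nan),
    n_carriers: int = 0,
) -> EquivalenceResult:
    """Find the top PRS fraction whose band risk at the anchor age is
    nearest the target (carrier) risk.

    The KM band risk is a noisy step function of q, so the whole
    0.5-percentile grid is evaluated and the smallest grid fraction with
    risk closest to the target wins (ties go to the smaller fraction).
    Raises if the target lies outside the achievable range.
    """
    q_lo, q_hi = search_bounds
    # grid at whole multiples of the step (0.5%, 1%, ...), plus the bounds
    start = np.ceil(q_lo / grid_step - 1e-9) * grid_step
    grid = np.round(np.arange(start, q_hi + 1e-12, grid_step), 10)
    grid = np.unique(np.concatenate([[q_lo], grid, [q_hi]]))

    evaluated = [_top_band_risk(frame, score, q, anchor_age, mode) for q in grid]
    risks = np.array([r for r, _, _ in evaluated])
    hi_r, lo_r = float(risks.max()), float(risks.min())
    if not lo_r <= target_risk <= hi_r:
        raise EstimationError(
            f"target risk {target_risk:.4g} outside achievable range "
            f"[{lo_r:.4g}, {hi_r:.4g}] at age {anchor_age:g} "
            f"for top fractions in [{q_lo}, {q_hi}]"
        )
    best = int(np.argmin(np.abs(risks - target_risk)))  # argmin: first minimum
    best_q = float(grid[best])
    best_risk, best_ci, best_n = evaluated[best]
    return EquivalenceResult(
        carrier_risk=float(target_risk), carrier_ci=carrier_ci,
        matched_fraction=float(best_q), matched_band_risk=float(best_risk),
        matched_band_ci=best_ci, anchor_age=anchor_age,
        subgroup_filter=subgroup_filter, n_carriers=n_carriers, n_band=best_n,
    )


def case_ratio_by_age(
    frame: AnalysisFrame,
    score: str,
    top_fraction: float,
    carriers: CarrierTable,
    cutoffs: list[float] = [50.0, 60.0, 70.0],
) -> CaseRatioResult:
    """Diagnosed-case counts before each age cutoff: top-q band vs
    carriers, with their ratio.  Individuals in both groups count in both;
    the overlap is reported together with its expectation under
    independence."""
    df = _merge_carriers(frame, carriers)
    pct = percentile_ranks(df[score], df["individual_id"])
    in_band = pct > 100 * (1 - top_fraction)
    is_carrier = (df["carrier_flag"] == 1).to_numpy()
    if in_band.sum() == 0 or is_carrier.sum() == 0:
        raise EstimationError("band or carrier group is empty")
    case = (df["case_flag"] == 1).to_numpy()
    event_age = df["event_age"].to_numpy(dtype=float)
    band_cases, carrier_cases, ratios = [], [], []
    for cut in cutoffs:
        before = case & (event_age < cut)
        nb = int((before & in_band).sum())
        nc = int((before & is_carrier).sum())
        band_cases.append(nb)
        carrier_cases.append(nc)
        ratios.append(nb / nc if nc > 0 else None)
    overlap = int((in_band & is_carrier).sum())
    expected = float(in_band.sum() * is_carrier.sum() / len(df))
    return CaseRatioResult(
        cutoffs=list(cutoffs), band_cases=band_cases, carrier_cases=carrier_cases,
        ratios=ratios, top_fraction=top_fraction,
        overlap_count=overlap, overlap_expected=expected,
    )


def prs_modulation_of_carriers(
    frame: AnalysisFrame,
    score: str,
    carriers: CarrierTable,
    bands: list[tuple[float, float]] = [(90.0, 100.0), (40.0, 60.0), (0.0, 10.0)],
    mode: str = "lifetime",
    min_cases_curve: int | None = 40,
) -> dict[str, IncidenceCurve]:
    """KM incidence among carriers, stratified by the carrier's PRS band.

    Bands are defined on the *full-cohort* PRS distribution, then applied
    to the carrier subgroup.  Raises only if every band falls below the
    curve gate; individual bands may come back suppressed.
    """
    df = _merge_carriers(frame, carriers)
    pct = percentile_ranks(df[score], df["individual_id"])
    is_carrier = (df["carrier_flag"] == 1).to_numpy()
    out: dict[str, IncidenceCurve] = {}
    any_ok = False
    for lo, hi in bands:
        band = PercentileBand(lo, hi)
        mask = (pct > lo) & (pct <= hi) & is_carrier
        sub = AnalysisFrame(
            data=df[mask].reset_index(drop=True), trait_code=frame.trait_code,
            kind=frame.kind, dropped=frame.dropped,
            sex_restriction=frame.sex_restriction, age_window=frame.age_window,
        )
        if sub.n == 0:
            curve = IncidenceCurve(
                band=band, grid=np.array([]), cum_inc=np.array([]),
                ci_low=np.array([]), ci_high=np.array([]), n_at_risk=np.array([]),
                n_events=0, n_members=0, mode=mode, suppressed=True,
                gate_reason="no carriers in band",
            )
        else:
            curve = km_curve(sub, mode=mode, band=band, min_cases_curve=min_cases_curve)
        out[band.label] = curve
        any_ok = any_ok or not curve.suppressed
    if not any_ok:
        raise EstimationError("every PRS band of the carrier group is below the curve gate")
    return out
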