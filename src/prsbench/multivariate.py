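"""Cross-PRS correlation structure and multi-PRS all-cause-mortality models.

With scores for many traits on the same individuals, two questions arise:
how correlated are the scores (answered by a Pearson correlation matrix,
ordered by complete-linkage hierarchical clustering for display), and how
much do they jointly explain of all-cause mortality.  The mortality model
is a forward-stepwise Cox regression of time from first assessment to
death, run either on participants' own survival (covariates: age at
assessment, sex) or on their parents' lifespans (one observation per
parent, covariates: participant's age at assessment and the parent's sex).
Because a parent shares half their common variation with the offspring,
the offspring's PRS should carry about half its own-mortality log-hazard
into the parental model — the 2:1 own:parent expectation that
``parent_offspring_ratio`` quantifies.

Model quality is summarised by Harrell's concordance C (with a paired
bootstrap CI on the change between nested models) and Royston &
Sauerbrei's D-based explained variation R^2_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from ._cox import CoxFit, coxph_fit
from .cohort import CohortTable, ScoreSet
from .errors import EstimationError
from .metrics import Z95

KAPPA = float(np.sqrt(8 / np.pi))   # scaling of the rank-based D statistic
SIGMA2 = float(np.pi**2 / 6)        # variance of the standard extreme-value error


@dataclass
class CorrelationMatrix:
    names: list[str]
    values: np.ndarray
    subgroup: str = ""
    order: list[str] | None = None   # clustering leaf order, once computed
    undefined: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "values": [[None if np.isnan(v) else float(v) for v in row]
                       for row in self.values],
            "subgroup": self.subgroup,
            "order": self.order,
            "undefined": self.undefined,
        }


@dataclass
class MortalityModel:
    target: str                       # "own" | "parental"
    selected: list[str]
    log_hr: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    baseline_covariates: list[str]
    n: int
    n_events: int
    entry_p: float
    removal_p: float
    fit: CoxFit | None = None

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "selected": self.selected,
            "log_hr": self.log_hr,
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "baseline_covariates": self.baseline_covariates,
            "n": self.n,
            "n_events": self.n_events,
            "entry_p": self.entry_p,
            "removal_p": self.removal_p,
        }


def prs_correlation_matrix(
    scores: ScoreSet,
    subgroup_mask: np.ndarray | None = None,
    subgroup: str = "",
) -> CorrelationMatrix:
    """Pairwise complete-case Pearson correlations between score columns.

    One triangle is computed and mirrored, so the stored matrix is exactly
    symmetric.  Constant columns are flagged and their row/column is NaN.
    """
    names = sorted(scores.score_names)
    if len(names) < 2:
        raise EstimationError("need at least two scores for a correlation matrix")
    df = scores.data if subgroup_mask is None else scores.data[np.asarray(subgroup_mask, bool)]
    if len(df) < 3:
        raise EstimationError("need at least three individuals")
    M = np.eye(len(names))
    undefined = [n for n in names if df[n].dropna().nunique() <= 1]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if names[i] in undefined or names[j] in undefined:
                r = np.nan
            else:
                pair = df[[names[i], names[j]]].dropna()
                r = float(pair[names[i]].corr(pair[names[j]]))
            M[i, j] = M[j, i] = r
    for n in undefined:
        k = names.index(n)
        M[k, k] = np.nan
    return CorrelationMatrix(names=names, values=M, subgroup=subgroup, undefined=undefined)


def cluster_order(matrix: CorrelationMatrix) -> list[str]:
    """Dendrogram leaf order from complete-linkage clustering of the
    correlation rows (Euclidean distance).  Rows enter the linkage in
    name order, which fixes tie-breaking and makes the result invariant
    to the caller's row permutation."""
    if matrix.undefined:
        raise EstimationError(
            f"correlation matrix has undefined rows: {matrix.undefined}"
        )
    # names are sorted at construction; re-sort defensively
    idx = np.argsort(matrix.names)
    names = [matrix.names[i] for i in idx]
    rows = matrix.values[np.ix_(idx, idx)]
    Z = linkage(rows, method="complete", metric="euclidean")
    order = [names[i] for i in leaves_list(Z)]
    matrix.order = order
    return order


def _mortality_frame(
    cohort: CohortTable, scores: ScoreSet, target: str
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Build (covariate frame, durations, events, baseline names)."""
    df = cohort.data.merge(scores.data, on="individual_id", how="inner")
    df = df[df["sex"].notna()]
    if target == "own":
        dur = (df["censor_age"] - df["age_at_assessment"]).to_numpy(dtype=float)
        dead = df["death_age"].notna() & (df["death_age"] <= df["censor_age"])
        ev = dead.to_numpy(dtype=int)
        keep = dur > 0
        df, dur, ev = df[keep], dur[keep], ev[keep]
        base = pd.DataFrame({
            "age_at_assessment": df["age_at_assessment"].to_numpy(dtype=float),
            "sex_male": (df["sex"] == "male").to_numpy(dtype=float),
        }, index=df.index)
        baseline = ["age_at_assessment", "sex_male"]
    elif target == "parental":
        if cohort.parents is None or cohort.parents.empty:
            raise EstimationError("cohort has no parental records")
        par = cohort.parents.merge(
            df[["individual_id", "age_at_assessment"] + scores.score_names],
            on="individual_id", how="inner",
        )
        dur = par["parent_age"].to_numpy(dtype=float)
        ev = par["parent_dead"].to_numpy(dtype=int)
        keep = dur > 0
        par, dur, ev = par[keep], dur[keep], ev[keep]
        base = pd.DataFrame({
            "age_at_assessment": par["age_at_assessment"].to_numpy(dtype=float),
            "parent_sex_male": (par["parent_sex"] == "male").to_numpy(dtype=float),
        }, index=par.index)
        baseline = ["age_at_assessment", "parent_sex_male"]
        df = par
    else:
        raise EstimationError(f"unknown mortality target {target!r}")
    frame = pd.concat([base, df[scores.score_names]], axis=1)
    return frame.reset_index(drop=True), dur, ev, baseline


def stepwise_mortality(
    cohort: CohortTable,
    scores: ScoreSet,
    target: str = "own",
    candidates: list[str] | None = None,
    entry_p: float = 0.001,
    removal_p: float = 0.001,
) -> MortalityModel:
    """Forward-stepwise Cox selection of PRSs predicting mortality.

    At each step the candidate with the smallest Wald p-value below
    ``entry_p`` enters (ties broken by p then name); after each entry, any
    selected score whose p rose above ``removal_p`` leaves.  Iterates to a
    fixpoint.  An empty model is a valid outcome.  Baseline covariates are
    always kept.
    """
    frame, dur, ev, baseline = _mortality_frame(cohort, scores, target)
    candidates = sorted(candidates if candidates is not None else scores.score_names)
    if ev.sum() == 0:
        raise EstimationError("no deaths observed; mortality model cannot be fit")
    selected: list[str] = []
    while True:
        changed = False
        best = None  # (p, name, fit)
        for name in candidates:
            if name in selected:
                continue
            cols = baseline + selected + [name]
            fit = coxph_fit(frame[cols].to_numpy(), dur, ev, names=cols)
            p = fit.p_values()[cols.index(name)]
            if p < entry_p and (best is None or (p, name) < (best[0], best[1])):
                best = (p, name, fit)
        if best is not None:
            selected.append(best[1])
            changed = True
        if selected:
            cols = baseline + selected
            fit = coxph_fit(frame[cols].to_numpy(), dur, ev, names=cols)
            pvals = fit.p_values()
            worst = max(
                ((pvals[cols.index(s)], s) for s in selected),
                default=None,
            )
            if worst is not None and worst[0] > removal_p:
                selected.remove(worst[1])
                changed = True
        if not changed:
            break

    cols = baseline + selected
    final = coxph_fit(frame[cols].to_numpy(), dur, ev, names=cols) if selected else None
    log_hr, se, ci = {}, {}, {}
    if final is not None:
        lo, hi = final.ci()
        for k, name in enumerate(cols):
            if name in selected:
                log_hr[name] = float(final.params[k])
                se[name] = float(final.se[k])
                ci[name] = (float(lo[k]), float(hi[k]))
    return MortalityModel(
        target=target, selected=selected, log_hr=log_hr, se=se, ci=ci,
        baseline_covariates=baseline, n=len(dur), n_events=int(ev.sum()),
        entry_p=entry_p, removal_p=removal_p, fit=final,
    )


def harrells_c(
    predictions: np.ndarray, durations: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's concordance: fraction of usable pairs where the higher
    predicted risk has the earlier event; prediction ties count 1/2."""
    ev = np.asarray(events, dtype=bool)
    if ev.sum() == 0:
        raise EstimationError("no events; no usable pairs for concordance")
    # concordance_index is oriented for 'higher prediction = longer survival'
    return float(concordance_index(durations, -np.asarray(predictions, float), ev))


def harrells_c_difference(
    pred_full: np.ndarray,
    pred_reduced: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Change in Harrell's C between nested models, paired bootstrap CI."""
    c_full = harrells_c(pred_full, durations, events)
    c_red = harrells_c(pred_reduced, durations, events)
    n = len(durations)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_bootstrap)
    pf = np.asarray(pred_full, float)
    pr = np.asarray(pred_reduced, float)
    dur = np.asarray(durations, float)
    ev = np.asarray(events, int)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if ev[idx].sum() == 0:
            diffs[b] = np.nan
            continue
        diffs[b] = harrells_c(pf[idx], dur[idx], ev[idx]) - harrells_c(
            pr[idx], dur[idx], ev[idx]
        )
    diffs = diffs[~np.isnan(diffs)]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    se = float(np.std(diffs, ddof=1))
    delta = c_full - c_red
    p = float(2 * stats.norm.sf(abs(delta / se))) if se > 0 else 1.0
    return {
        "c_full": c_full, "c_reduced": c_red, "delta": float(delta),
        "ci_low": float(lo), "ci_high": float(hi), "p_value": p,
        "n_bootstrap": n_bootstrap, "seed": seed,
    }


def royston_r2(
    prognostic_index: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
) -> float:
    """Royston & Sauerbrei's R^2_D from a fitted model's prognostic index.

    The index is replaced by scaled normal order statistics (rank-based),
    a Cox model is fit on that single regressor to obtain the prognostic
    separation D, and R^2_D = (D^2/kappa^2) / (D^2/kappa^2 + pi^2/6) with
    kappa = sqrt(8/pi).  A constant index returns 0 by convention.
    """
    pi = np.asarray(prognostic_index, dtype=float)
    if np.all(pi == pi[0]):
        return 0.0
    n = len(pi)
    # Blom-style normal scores of the ranks of the prognostic index
    ranks = stats.rankdata(pi, method="average")
    z = stats.norm.ppf((ranks - 3 / 8) / (n + 1 / 4))
    reg = z / KAPPA
    fit = coxph_fit(reg.reshape(-1, 1), durations, events)
    D = float(fit.params[0])
    d2k = D**2 / KAPPA**2
    return float(d2k / (d2k + SIGMA2))


def parent_offspring_ratio(
    model_own: MortalityModel,
    model_parental: MortalityModel,
    score: str,
) -> dict:
    """Ratio of own to parental log-HR for one score, delta-method CI.

    2.0 is the expectation when the parental effect is carried solely by
    the half-shared polygenic component.
    """
    for m, lab in ((model_own, "own"), (model_parental, "parental")):
        if score not in m.log_hr:
            raise EstimationError(f"score {score!r} not in the {lab} mortality model")
    a, sa = model_own.log_hr[score], model_own.se[score]
    b, sb = model_parental.log_hr[score], model_parental.se[score]
    if abs(b) < 2 * sb:
        flagged = True
    else:
        flagged = False
    if b == 0:
        raise EstimationError("parental log-HR is exactly zero; ratio undefined")
    ratio = a / b
    var = sa**2 / b**2 + (a**2 / b**4) * sb**2
    se = float(np.sqrt(var))
    return {
        "score": score, "ratio": float(ratio), "se": se,
        "ci_low": float(ratio - Z95 * se), "ci_high": float(ratio + Z95 * se),
        "own_log_hr": float(a), "parental_log_hr": float(b),
        "weak_parental_signal": flagged,
    }
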