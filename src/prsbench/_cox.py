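"""Newton-Raphson Cox proportional-hazards fitter.

Breslow handling of tied event times, optional delayed entry (left
truncation), convergence declared when the Newton step's max-norm falls
below 1e-8 (100 iteration budget).  Written as the package's reference
Cox routine so that per-SD hazard ratios and the stepwise mortality model
share one well-characterised likelihood.

The partial log-likelihood with Breslow ties is

    l(b) = sum_events [ x_i'b - log( sum_{j in R(t_i)} exp(x_j'b) ) ]

with R(t) = {j : entry_j < t <= time_j}.  Risk-set sums are accumulated by
processing distinct event times in decreasing order and adding subjects as
they enter the risk set, which keeps each Newton iteration O(n log n + n p^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConvergenceError, EstimationError, SeparationError


@dataclass
class CoxFit:
    params: np.ndarray          # log-hazard ratios
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    names: list[str]

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.params - z * self.se, self.params + z * self.se

    def p_values(self) -> np.ndarray:
        z = self.params / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.params


def coxph_fit(
    X: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    entries: np.ndarray | None = None,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the Breslow partial likelihood.

    Parameters
    ----------
    X : (n, p) covariate matrix (no intercept; Cox has none).
    durations : event/censoring times (age or follow-up time).
    events : 1 = event observed, 0 = censored.
    entries : optional delayed-entry times (risk from entry < t <= duration).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(durations) > 1:
        X = X.T
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=int)
    n, p = X.shape
    if entries is None:
        entries = np.full(n, -np.inf)
    e = np.asarray(entries, dtype=float)
    if d.sum() == 0:
        raise EstimationError("no events observed; Cox model cannot be fit")
    if np.any(e >= t):
        raise EstimationError("entry time must precede event/censoring time")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [i for i, s in enumerate(sds) if s == 0]
        raise EstimationError(f"constant covariate column(s) at index {bad}")

    # sort once; all per-iteration work is vectorised over these indices
    order_t = np.argsort(t)[::-1]          # decreasing duration
    order_e = np.argsort(e)[::-1]          # decreasing entry
    t_sorted = t[order_t]
    e_sorted = e[order_e]

    # per distinct event time: number of events and sum of event covariates
    ev_idx = np.flatnonzero(d == 1)
    ord_ev = np.argsort(t[ev_idx], kind="stable")
    ev_t_sorted = t[ev_idx][ord_ev]
    starts = np.flatnonzero(
        np.concatenate([[True], ev_t_sorted[1:] != ev_t_sorted[:-1]])
    )
    event_times = ev_t_sorted[starts]
    d_counts = np.diff(np.append(starts, len(ev_t_sorted)))
    x_events = np.add.reduceat(X[ev_idx[ord_ev]], starts, axis=0)

    beta = np.zeros(p)
    for iteration in range(max_iter):
        eta = X @ beta
        eta_max = eta.max()
        eta = eta - eta_max  # guard overflow; restored in the log-likelihood
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = np.einsum("i,ij,ik->ijk", w, X, X)

        # prefix sums in decreasing-time order: S0_t[k] = sum of w over the
        # k subjects with largest durations (ties included progressively)
        cs0_t = np.concatenate([[0], np.cumsum(w[order_t])])
        cs1_t = np.concatenate([np.zeros((1, p)), np.cumsum(wX[order_t], axis=0)])
        cs2_t = np.concatenate([np.zeros((1, p, p)), np.cumsum(wXX[order_t], axis=0)])
        cs0_e = np.concatenate([[0], np.cumsum(w[order_e])])
        cs1_e = np.concatenate([np.zeros((1, p)), np.cumsum(wX[order_e], axis=0)])
        cs2_e = np.concatenate([np.zeros((1, p, p)), np.cumsum(wXX[order_e], axis=0)])

        # at event time tk: risk set = {time >= tk} \ {entry >= tk}
        k_t = np.searchsorted(-t_sorted, -event_times, side="right")
        k_e = np.searchsorted(-e_sorted, -event_times, side="right")
        S0 = cs0_t[k_t] - cs0_e[k_e]
        S1 = cs1_t[k_t] - cs1_e[k_e]
        S2 = cs2_t[k_t] - cs2_e[k_e]
        if np.any(S0 <= 0):
            raise EstimationError("empty risk set at an event time (check entry times)")

        ll = float((x_events @ beta).sum() - (d_counts * (np.log(S0) + eta_max)).sum())
        grad = (x_events - d_counts[:, None] * S1 / S0[:, None]).sum(axis=0)
        Ebar = S1 / S0[:, None]
        info = (
            d_counts[:, None, None]
            * (S2 / S0[:, None, None] - np.einsum("ij,ik->ijk", Ebar, Ebar))
        ).sum(axis=0)

        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        if np.max(np.abs(step)) > 10:
            # monotone likelihood walks the coefficient to infinity
            if np.max(np.abs(beta)) > 50:
                raise SeparationError("monotone partial likelihood (infinite estimate)")
            step = step / np.max(np.abs(step)) * 1.0  # damped step
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")

    if np.max(np.abs(beta)) > 50:
        raise SeparationError("monotone partial likelihood (estimate diverged)")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        params=beta,
        se=se,
        cov=cov,
        loglik=ll,
        n=n,
        n_events=int(d.sum()),
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )
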