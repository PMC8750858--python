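"""Age-period-cohort decomposition of event rates on an aggregated grid.

Event counts on an age-group x period grid (with exposures) are modelled by
a Poisson working model with log link: age and period enter as sum-to-zero
fixed effects, and the cohort (diagonal ``cohort = period - age``) as a
random effect realized as an L2 (ridge) penalty on the cohort contrasts.
The ridge resolves the classical APC identification problem: the linear
time trend shared by age, period and cohort is attributed to the fixed
axes, and the cohort variance is chosen by a Laplace-approximate marginal
likelihood over a fixed log-spaced grid.

The period fixed effects estimate calendar-time (annual policy) shifts and
can be subtracted from scores or log-rates via :func:`period_adjust`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ApcModel", "fit_apc", "period_adjust", "cohort_index"]


def cohort_index(age_group: int, period: int) -> int:
    """The APC identity: cohort = period - age."""
    return period - age_group


@dataclass
class ApcModel:
    """Fitted APC effects on the log-rate scale."""

    intercept: float
    age_effects: pd.Series  # indexed by age group, sum-to-zero
    period_effects: pd.Series  # indexed by period, sum-to-zero
    cohort_effects: pd.Series  # indexed by cohort = period - age
    cohort_var: float
    deviance: float

    def linear_predictor(self, age_group, period) -> np.ndarray:
        age_group = np.atleast_1d(age_group)
        period = np.atleast_1d(period)
        co = period - age_group
        return (
            self.intercept
            + self.age_effects.reindex(age_group).fillna(0.0).to_numpy()
            + self.period_effects.reindex(period).fillna(0.0).to_numpy()
            + self.cohort_effects.reindex(co).fillna(0.0).to_numpy()
        )


def _sum_to_zero(levels: np.ndarray) -> np.ndarray:
    """contr.sum coding: k levels -> k-1 columns, last level = -sum of others."""
    k = len(levels)
    C = np.zeros((k, k - 1))
    C[:-1, :] = np.eye(k - 1)
    C[-1, :] = -1.0
    return C


def _design(cells: pd.DataFrame):
    ages = np.sort(cells["age_group"].unique())
    periods = np.sort(cells["period"].unique())
    cohorts = np.sort((cells["period"] - cells["age_group"]).unique())
    Ca = _sum_to_zero(ages)
    Cp = _sum_to_zero(periods)
    ai = pd.Index(ages).get_indexer(cells["age_group"])
    pi = pd.Index(periods).get_indexer(cells["period"])
    ci = pd.Index(cohorts).get_indexer(cells["period"] - cells["age_group"])
    n = len(cells)
    Xa = Ca[ai]
    Xp = Cp[pi]
    Xc = np.zeros((n, len(cohorts)))
    Xc[np.arange(n), ci] = 1.0
    X = np.hstack([np.ones((n, 1)), Xa, Xp, Xc])
    n_fixed = 1 + Xa.shape[1] + Xp.shape[1]
    return X, n_fixed, ages, periods, cohorts, Ca, Cp


def _fit_penalized_poisson(X, d, log_E, lam, n_fixed, max_iter=200, tol=1e-9):
    """IRLS for a Poisson log-link model with ridge penalty lam on the
    trailing (cohort) block. Returns (theta, penalized Hessian, loglik)."""
    n, p = X.shape
    pen = np.zeros(p)
    pen[n_fixed:] = lam
    P = np.diag(pen)
    theta = np.zeros(p)
    theta[0] = np.log(max(d.sum(), 0.5)) - np.log(np.exp(log_E).sum())
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ theta + log_E
        mu = np.exp(np.clip(eta, -30, 30))
        ll = float(np.sum(d * eta - mu))
        g = X.T @ (d - mu) - pen * theta
        H = X.T @ (mu[:, None] * X) + P
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        theta = theta + step
        if abs(ll - ll_old) < tol and np.max(np.abs(g)) < 1e-6:
            break
        ll_old = ll
    eta = X @ theta + log_E
    mu = np.exp(np.clip(eta, -30, 30))
    ll = float(np.sum(d * eta - mu))
    H = X.T @ (mu[:, None] * X) + P
    return theta, H, ll


def fit_apc(cells: pd.DataFrame, lambda_grid=None) -> ApcModel:
    """Fit the APC model on a cell table ``(age_group, period, events, exposure)``.

    ``lambda_grid`` is the ridge grid for the cohort random effect (default
    log-spaced 1e-1 .. 1e5); the value maximizing the Laplace-approximate
    marginal likelihood is selected and ``cohort_var = 1/lambda``.
    """
    required = {"age_group", "period", "events", "exposure"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells must have columns {sorted(required)}")
    cells = cells.reset_index(drop=True)
    if cells["period"].nunique() < 2:
        raise ValueError("need at least two periods for an APC fit")
    if cells["age_group"].nunique() < 2:
        raise ValueError("need at least two age groups for an APC fit")
    if np.any(cells["exposure"] <= 0):
        raise ValueError("exposures must be positive")

    X, n_fixed, ages, periods, cohorts, Ca, Cp = _design(cells)
    d = cells["events"].to_numpy(dtype=float)
    log_E = np.log(cells["exposure"].to_numpy(dtype=float))
    if lambda_grid is None:
        lambda_grid = np.logspace(-1, 5, 13)

    K = len(cohorts)
    best = None
    for lam in lambda_grid:
        theta, H, ll = _fit_penalized_poisson(X, d, log_E, lam, n_fixed)
        gamma = theta[n_fixed:]
        # Laplace approximation to the marginal likelihood of the cohort block
        Hcc = H[n_fixed:, n_fixed:]
        sign, logdet = np.linalg.slogdet(Hcc)
        if sign <= 0:
            continue
        mll = ll - 0.5 * lam * float(gamma @ gamma) + 0.5 * K * np.log(lam) - 0.5 * logdet
        if best is None or mll > best[0]:
            best = (mll, lam, theta, H, ll)
    if best is None:
        raise RuntimeError("APC fit failed for every ridge value")
    _, lam, theta, H, ll = best

    a = Ca @ theta[1 : 1 + Ca.shape[1]]
    p_eff = Cp @ theta[1 + Ca.shape[1] : n_fixed]
    gamma = theta[n_fixed:]
    eta = X @ theta + log_E
    mu = np.exp(np.clip(eta, -30, 30))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * float(np.sum(np.where(d > 0, d * np.log(d / mu), 0.0) - (d - mu)))
    return ApcModel(
        intercept=float(theta[0]),
        age_effects=pd.Series(a, index=pd.Index(ages, name="age_group")),
        period_effects=pd.Series(p_eff, index=pd.Index(periods, name="period")),
        cohort_effects=pd.Series(gamma, index=pd.Index(cohorts, name="cohort")),
        cohort_var=float(1.0 / lam),
        deviance=dev,
    )


def period_adjust(values, periods, apc: ApcModel) -> np.ndarray:
    """Remove the fitted period effect from linear-predictor-scale values.

    ``values`` are log-rates or scores aligned with ``periods``; the fitted
    period fixed effect is subtracted, leaving within-period ordering
    untouched.  Unseen periods get zero adjustment.
    """
    values = np.asarray(values, dtype=float)
    periods = np.atleast_1d(periods)
    adj = apc.period_effects.reindex(periods).fillna(0.0).to_numpy()
    return values - adj
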