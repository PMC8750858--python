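"""Cox proportional-hazards fitting used to seed hierarchy weights.

The partial likelihood (Breslow handling of tied event times) is maximized
by Newton iterations with step-halving; the observed information matrix
supplies standard errors, Wald z statistics and 95% CIs for the hazard
ratios.  The magnitudes of the fitted log-hazard coefficients seed the
pairwise-comparison matrices of the factor hierarchy, so protective and
harmful effects contribute symmetrically to importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ahp import ConvergenceError

__all__ = ["CoxModel", "fit_cox", "cox_weight_seed"]

_Z95 = 1.959963984540054


@dataclass
class CoxModel:
    """Fitted Cox model: per-covariate beta, SE, HR with 95% CI, z."""

    summary: pd.DataFrame  # index covariate; columns beta, se, hr, ci_low, ci_high, z
    loglik: float
    n: int
    n_events: int
    iterations: int

    @property
    def beta(self) -> pd.Series:
        return self.summary["beta"]

    def to_csv(self, path) -> None:
        out = self.summary.rename(
            columns={"beta": "Coefficient", "ci_low": "CI low", "ci_high": "CI high", "z": "z"}
        )[["Coefficient", "CI low", "CI high", "z", "hr", "se"]]
        out.to_csv(path, index_label="covariate")


def _breslow_negloglik_grad_hess(beta, X, order, first_tie, event_pos):
    """Log-likelihood, gradient and Hessian of the Breslow partial likelihood.

    ``order`` sorts times ascending; ``first_tie[i]`` is the first sorted
    position sharing row i's time; ``event_pos`` are sorted positions of
    events.
    """
    Xs = X[order]
    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; cancels in ratios
    r = np.exp(eta)
    # reverse cumulative sums over the risk set {j : t_j >= t_i}
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
    f = first_tie[event_pos]
    xb = Xs[event_pos]
    ll = float(np.sum(eta[event_pos] - np.log(S0[f])))
    mbar = S1[f] / S0[f][:, None]
    grad = (xb - mbar).sum(axis=0)
    hess = -(S2[f] / S0[f][:, None, None] - mbar[:, :, None] * mbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def fit_cox(
    t,
    e,
    X: pd.DataFrame,
    tol: float = 1e-7,
    max_iter: int = 50,
) -> CoxModel:
    """Fit a Cox model of event times ``t`` (censoring flag ``e``) on ``X``.

    Constant columns are dropped with a warning.  Raises
    :class:`ConvergenceError` (carrying the last iterate) on separation or
    non-convergence; convergence is declared when the gradient sup-norm
    falls below ``tol``.
    """
    X = pd.DataFrame(X)
    t = np.asarray(t, dtype=float)
    e = np.asarray(e).astype(int)
    if np.any(t <= 0):
        raise ValueError("durations must be strictly positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event flag must be binary")
    if len(X) != t.size or t.size != e.size:
        raise ValueError("t, e and X must have equal length")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant covariates: {const}")
        X = X.drop(columns=const)
    names = list(X.columns)
    V = X.to_numpy(dtype=float)
    # center for numerical stability (does not change beta)
    V = V - V.mean(axis=0)
    n, p = V.shape
    if p == 0:
        raise ValueError("no non-constant covariates")

    order = np.argsort(t, kind="stable")
    ts = t[order]
    # first index of each tie group among sorted times
    first_tie = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_tie[i] = first_tie[i - 1] if ts[i] == ts[i - 1] else i
    event_pos = np.flatnonzero(e[order] == 1)
    if event_pos.size == 0:
        raise ValueError("no events observed")

    beta = np.zeros(p)
    ll, grad, hess = _breslow_negloglik_grad_hess(beta, V, order, first_tie, event_pos)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                f"singular information matrix (separation or collinearity): {err}",
                last=pd.Series(beta, index=names),
            ) from err
        # step-halving: the partial likelihood never decreases across accepted steps
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _breslow_negloglik_grad_hess(
                cand, V, order, first_tie, event_pos
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                "step-halving failed to improve the partial likelihood",
                last=pd.Series(beta, index=names),
            )
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        if np.max(np.abs(grad)) >= tol:
            raise ConvergenceError(
                f"Newton iterations did not converge in {max_iter} steps "
                f"(|grad|={np.max(np.abs(grad)):.3g})",
                last=pd.Series(beta, index=names),
            )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - _Z95 * se),
            "ci_high": np.exp(beta + _Z95 * se),
            "z": beta / se,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxModel(summary=summary, loglik=ll, n=n, n_events=int(event_pos.size), iterations=it)


def cox_weight_seed(
    m: CoxModel, factors: list[str] | None = None, significant_only: bool = False
) -> pd.Series:
    """Normalized |beta| magnitudes as hierarchy weight seeds.

    ``factors`` restricts/orders the output; ``significant_only`` zeroes
    coefficients with |z| < 1.96 before normalizing (off by default).  When
    every beta is zero an equal-weight vector is returned with a warning.
    """
    if factors is None:
        factors = list(m.summary.index)
    missing = [f for f in factors if f not in m.summary.index]
    if missing:
        raise KeyError(f"no fitted coefficient for factors: {missing}")
    mag = m.summary.loc[factors, "beta"].abs()
    if significant_only:
        mag = mag.where(m.summary.loc[factors, "z"].abs() >= _Z95, 0.0)
    if mag.sum() == 0:
        warnings.warn("all coefficient magnitudes are zero; using equal weights")
        mag = pd.Series(1.0, index=mag.index)
    return mag / mag.sum()
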