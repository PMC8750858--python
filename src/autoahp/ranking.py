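"""Six-indicator feature-importance ensemble for screening cohort variables.

Candidate variables are scored by information gain, gain ratio, Gini gain,
the Pearson chi-square statistic, ReliefF and FCBF symmetric uncertainty
against the binary risk-event outcome; the per-indicator ranks are averaged
into an ensemble rank used (together with expert keep/drop lists) to screen
the variable set down to the modelled factors.

Entropies are in bits so that a perfect predictor of a balanced outcome
scores exactly 1 bit of information gain.  Continuous variables should be
discretized (see :mod:`autoahp.discretize`) before the entropy-based
indicators are applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, rankdata
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "entropy",
    "info_gain",
    "gain_ratio",
    "gini_gain",
    "chi_square",
    "symmetric_uncertainty",
    "relieff",
    "fcbf",
    "rank_features",
    "ensemble_rank",
    "select_features",
]


def _check_xy(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same length")
    return x, y


def entropy(x) -> float:
    """Shannon entropy of a discrete sample, in bits."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty input")
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _conditional_entropy(x, y) -> float:
    vals, inv = np.unique(x, return_inverse=True)
    h = 0.0
    n = len(x)
    for v in range(len(vals)):
        mask = inv == v
        h += mask.sum() / n * entropy(y[mask])
    return h


def info_gain(x, y) -> float:
    """IG = H(y) - H(y|x), in bits (nonnegative)."""
    x, y = _check_xy(x, y)
    return max(0.0, entropy(y) - _conditional_entropy(x, y))


def gain_ratio(x, y) -> float:
    """IG normalized by H(x); 0 when x is constant."""
    x, y = _check_xy(x, y)
    hx = entropy(x)
    if hx == 0.0:
        return 0.0
    return info_gain(x, y) / hx


def _gini(y) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def gini_gain(x, y) -> float:
    """Gini impurity of y minus its x-conditional mixture (nonnegative)."""
    x, y = _check_xy(x, y)
    vals, inv = np.unique(x, return_inverse=True)
    n = len(x)
    cond = 0.0
    for v in range(len(vals)):
        mask = inv == v
        cond += mask.sum() / n * _gini(y[mask])
    return max(0.0, _gini(y) - cond)


def chi_square(x, y) -> float:
    """Pearson chi-square statistic of the x-by-y contingency table.

    Zero rows/columns are dropped (with a warning) before evaluation.
    """
    x, y = _check_xy(x, y)
    table = pd.crosstab(pd.Series(x, name="x"), pd.Series(y, name="y")).to_numpy()
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        table = table[keep_r][:, keep_c]
    if min(table.shape) < 2:
        return 0.0
    stat, _, _, _ = chi2_contingency(table, correction=False)
    return float(stat)


def symmetric_uncertainty(x, y) -> float:
    """SU(x, y) = 2 IG / (H(x) + H(y)), a normalized mutual information in [0, 1]."""
    x, y = _check_xy(x, y)
    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0.0:
        return 0.0
    return min(1.0, 2.0 * info_gain(x, y) / (hx + hy))


def relieff(
    X: pd.DataFrame,
    y,
    k_neighbors: int = 10,
    n_samples: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """ReliefF feature weights in [-1, 1].

    For each sampled instance the weight of feature *f* decreases with its
    distance to the k nearest same-class neighbours (hits) and increases
    with the class-prior-weighted distance to the k nearest neighbours of
    every other class (misses).  Features are min-max scaled internally so
    per-feature differences lie in [0, 1].
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty input")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    cols = list(X.columns)
    V = X.to_numpy(dtype=float)
    rng_ = V.max(axis=0) - V.min(axis=0)
    nonconst = rng_ > 0
    V = np.where(nonconst, (V - V.min(axis=0)) / np.where(rng_ > 0, rng_, 1.0), 0.0)

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / counts.sum()))
    if np.any(counts - 1 < k_neighbors):
        warnings.warn("k_neighbors exceeds a class count; clipping")
    nn_by_class = {}
    idx_by_class = {}
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        idx_by_class[c] = idx
        nn_by_class[c] = NearestNeighbors(
            n_neighbors=min(k_neighbors + 1, cnt), metric="euclidean"
        ).fit(V[idx])

    rng = np.random.default_rng(seed)
    n = len(y)
    if n_samples is None or n_samples >= n:
        sample = np.arange(n)
    else:
        sample = rng.choice(n, size=n_samples, replace=False)

    W = np.zeros(V.shape[1])
    m = len(sample)
    for i in sample:
        ci = y[i]
        # hits: same class, excluding the instance itself
        nn = nn_by_class[ci]
        _, ind = nn.kneighbors(V[i : i + 1])
        hit_idx = idx_by_class[ci][ind[0]]
        hit_idx = hit_idx[hit_idx != i][: k_neighbors]
        if hit_idx.size:
            W -= np.abs(V[hit_idx] - V[i]).mean(axis=0) / m
        # misses: every other class, weighted by its prior among misses
        for c in classes:
            if c == ci:
                continue
            k_eff = min(k_neighbors, len(idx_by_class[c]))
            _, ind = nn_by_class[c].kneighbors(V[i : i + 1], n_neighbors=k_eff)
            miss_idx = idx_by_class[c][ind[0]]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * np.abs(V[miss_idx] - V[i]).mean(axis=0) / m
    W = np.where(nonconst, W, 0.0)
    return pd.Series(np.clip(W, -1.0, 1.0), index=cols, name="relieff")


def fcbf(X: pd.DataFrame, y, su_threshold: float = 0.0) -> pd.Series:
    """Fast correlation-based filter: selected features with their SU values.

    Features with SU(f, y) >= ``su_threshold`` are ordered by relevance;
    a feature f_j is pruned when an already-kept, more relevant feature
    f_i satisfies SU(f_i, f_j) >= SU(f_j, y) (f_i predominates f_j).
    Returns a Series of SU values indexed by the surviving feature names.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty input")
    su_y = {c: symmetric_uncertainty(X[c].to_numpy(), y) for c in X.columns}
    order = sorted((c for c in X.columns if su_y[c] >= su_threshold),
                   key=lambda c: (-su_y[c], str(c)))
    kept: list = []
    for cand in order:
        dominated = any(
            symmetric_uncertainty(X[k].to_numpy(), X[cand].to_numpy()) >= su_y[cand]
            for k in kept
        )
        if not dominated:
            kept.append(cand)
    return pd.Series({c: su_y[c] for c in kept}, name="fcbf", dtype=float)


_INDICATORS = ("info_gain", "gain_ratio", "gini", "chi2", "relieff", "fcbf")


def rank_features(
    X: pd.DataFrame,
    y,
    k_neighbors: int = 10,
    n_samples: int | None = None,
    su_threshold: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every column of ``X`` by the six indicators and ensemble-rank them.

    ``X`` is assumed discrete/discretized.  FCBF values are NaN for pruned
    features; NaN cells are excluded from that feature's mean rank.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    rows = {}
    rel = relieff(X, y, k_neighbors=k_neighbors, n_samples=n_samples, seed=seed)
    sel = fcbf(X, y, su_threshold=su_threshold)
    for c in X.columns:
        xv = X[c].to_numpy()
        rows[c] = {
            "info_gain": info_gain(xv, y),
            "gain_ratio": gain_ratio(xv, y),
            "gini": gini_gain(xv, y),
            "chi2": chi_square(xv, y),
            "relieff": rel[c],
            "fcbf": sel.get(c, np.nan),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(_INDICATORS)]
    table.index.name = "feature"
    return ensemble_rank(table)


def ensemble_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Append the mean-of-ranks column and sort best-first.

    Rank 1 is the highest indicator value; ties get midpoint ranks; NaN
    (undefined / not-selected) cells do not enter that feature's average.
    Final ordering is ascending mean rank with name as the deterministic
    tie-break.
    """
    table = table.copy()
    ranks = pd.DataFrame(index=table.index)
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        r = np.full(len(vals), np.nan)
        if ok.any():
            r[ok] = rankdata(-vals[ok], method="average")
        ranks[col] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        table["ensemble_rank"] = ranks.mean(axis=1, skipna=True)
    table = table.loc[sorted(table.index, key=str)]  # deterministic tie-break
    return table.sort_values("ensemble_rank", kind="stable")


def select_features(
    ranked: pd.DataFrame,
    keep_k: int = 23,
    expert_keep: list | tuple = (),
    expert_drop: list | tuple = (),
) -> list:
    """Top-k features by ensemble rank, then expert keeps added and drops removed."""
    order = list(ranked.sort_values("ensemble_rank").index)
    chosen = order[:keep_k]
    for f in expert_keep:
        if f not in chosen:
            chosen.append(f)
    return [f for f in chosen if f not in set(expert_drop)]
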