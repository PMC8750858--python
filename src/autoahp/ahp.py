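"""Reciprocal pairwise-comparison matrices for the analytic hierarchy process.

A pairwise comparison matrix ``A = (a_ij)`` encodes relative importance
judgements between the children of a hierarchy node on Saaty's 1-9 scale
(``a_ij`` is how much more important element *i* is than element *j*;
``a_ji = 1/a_ij``).  Priorities are the normalized principal (Perron)
eigenvector of ``A``, and judgement coherence is measured by the
consistency index ``CI = (lambda_max - n)/(n - 1)`` and consistency ratio
``CR = CI/RI`` against the order-dependent random index ``RI``; a matrix
is accepted when ``CR < 0.10``.

This module supports the *automatic* construction route: a nonnegative
weight vector (e.g. learned from Cox coefficients) is turned into the
perfectly consistent ratio matrix ``a_ij = w_i/w_j``, optionally snapped
to the admissible Saaty grid, and repaired if the snap pushed ``CR``
above the acceptance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SAATY_GRADES",
    "SAATY_VALUES",
    "AHPError",
    "ConvergenceError",
    "ConsistencyReport",
    "PairwiseMatrix",
    "saaty_value",
    "quantize_ratio",
    "matrix_from_weights",
    "principal_weights",
    "lambda_max_estimate",
    "consistency_index",
    "consistency_ratio",
    "consistency_report",
    "repair_matrix",
    "random_index",
]


class AHPError(ValueError):
    """Invalid pairwise-comparison input."""


class ConvergenceError(RuntimeError):
    """An iterative solve failed; ``.last`` carries the final iterate."""

    def __init__(self, message: str, last=None):
        super().__init__(message)
        self.last = last


#: The nine verbal importance grades of the 1-9 comparison scale.  Even
#: values are the intermediate grades lying between the two odd neighbours.
SAATY_GRADES: dict[str, int] = {
    "equal": 1,
    "intermediate_1": 2,
    "moderate": 3,
    "intermediate_2": 4,
    "essential": 5,
    "intermediate_3": 6,
    "strong": 7,
    "intermediate_4": 8,
    "extreme": 9,
}

#: Admissible matrix entries: 1/9 .. 1/2, 1, 2 .. 9 (17 values).
SAATY_VALUES: np.ndarray = np.concatenate(
    [1.0 / np.arange(9, 1, -1), np.arange(1, 10, dtype=float)]
)

# Saaty's standard random-index table, indexed by matrix order n.
_RI_TABLE = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

CR_THRESHOLD = 0.10
MAX_ORDER = 9


def saaty_value(relation: str) -> float:
    """Scale value of a verbal importance grade.

    ``intermediate_n`` (n = 1..4) is the grade 2n lying between the odd
    grades 2n-1 and 2n+1.
    """
    try:
        return float(SAATY_GRADES[relation])
    except KeyError:
        raise AHPError(
            f"unknown importance grade {relation!r}; expected one of {sorted(SAATY_GRADES)}"
        ) from None


def random_index(n: int) -> float:
    """Standard random index RI for a matrix of order ``n`` (n <= 9)."""
    if n < 1:
        raise AHPError(f"matrix order must be >= 1, got {n}")
    if n > MAX_ORDER:
        raise AHPError(f"matrix order {n} exceeds the supported maximum of {MAX_ORDER}")
    return _RI_TABLE[n]


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics of a pairwise comparison matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool

    def as_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "acceptable": self.acceptable,
        }


class PairwiseMatrix:
    """A positive reciprocal comparison matrix of order 2..9.

    Validates the unit diagonal and reciprocity on construction.  Entries
    are plain positive ratios; ``is_saaty`` reports whether every
    off-diagonal entry lies on the admissible 17-value grid.
    """

    def __init__(self, entries, *, tol: float = 1e-8):
        a = np.asarray(entries, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise AHPError(f"expected a square matrix, got shape {a.shape}")
        n = a.shape[0]
        if n < 2:
            raise AHPError("a pairwise comparison needs at least 2 elements")
        if n > MAX_ORDER:
            raise AHPError(f"matrix order {n} exceeds the supported maximum of {MAX_ORDER}")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise AHPError("entries must be finite and strictly positive")
        if not np.allclose(np.diag(a), 1.0, atol=tol):
            raise AHPError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, rtol=tol, atol=tol):
            raise AHPError("matrix is not reciprocal (a_ji != 1/a_ij)")
        self._a = a.copy()
        self._a.setflags(write=False)

    @property
    def values(self) -> np.ndarray:
        return self._a

    @property
    def n(self) -> int:
        return self._a.shape[0]

    @property
    def is_saaty(self) -> bool:
        off = self._a[~np.eye(self.n, dtype=bool)]
        return bool(np.all(np.min(np.abs(off[:, None] - SAATY_VALUES[None, :]), axis=1) < 1e-9))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairwiseMatrix(n={self.n})\n{self._a!r}"

    def __eq__(self, other) -> bool:
        return isinstance(other, PairwiseMatrix) and np.array_equal(self._a, other._a)

    def to_csv(self, path) -> None:
        """Write header-free n x n CSV."""
        np.savetxt(path, self._a, delimiter=",", fmt="%.12g")

    @classmethod
    def from_csv(cls, path) -> "PairwiseMatrix":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2))


_LOG_SAATY = np.log(SAATY_VALUES)


def quantize_ratio(r: float) -> float:
    """Snap a positive ratio to the nearest Saaty value in log-space.

    Symmetric in r and 1/r; ties break toward the smaller absolute grade
    (toward 1).
    """
    if not np.isfinite(r) or r <= 0:
        raise AHPError(f"ratio must be positive and finite, got {r}")
    d = np.abs(np.log(r) - _LOG_SAATY)
    best = d.min()
    candidates = np.flatnonzero(d <= best + 1e-12)
    # tie-break: smallest |log value| = closest to 1
    pick = candidates[np.argmin(np.abs(_LOG_SAATY[candidates]))]
    return float(SAATY_VALUES[pick])


WEIGHT_FLOOR = 1e-6


def _clean_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise AHPError("weight vector must be 1-D with length >= 2")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise AHPError("weights must be finite and nonnegative")
    if w.sum() <= 0:
        raise AHPError("weights must not all be zero")
    w = np.maximum(w, WEIGHT_FLOOR)  # keep ratios finite
    return w / w.sum()


def matrix_from_weights(w, quantize: bool = False) -> PairwiseMatrix:
    """Build the ratio matrix ``a_ij = w_i/w_j`` from a weight vector.

    Without quantization the result is perfectly consistent.  With
    ``quantize=True`` every upper-triangle ratio is snapped to the Saaty
    grid and the lower triangle filled with reciprocals.
    """
    w = _clean_weights(w)
    a = np.outer(w, 1.0 / w)
    if quantize:
        n = w.size
        for i in range(n):
            a[i, i] = 1.0
            for j in range(i + 1, n):
                q = quantize_ratio(a[i, j])
                a[i, j] = q
                a[j, i] = 1.0 / q
    return PairwiseMatrix(a)


def principal_weights(
    A: PairwiseMatrix, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    """Principal eigenvector (L1-normalized) and eigenvalue by power iteration.

    For any positive reciprocal matrix ``lambda_max >= n`` with equality
    iff the matrix is consistent.
    """
    a = A.values
    n = A.n
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v = a @ w
        v /= v.sum()
        if np.max(np.abs(v - w)) < tol:
            w = v
            break
        w = v
    else:
        raise ConvergenceError(
            f"power iteration did not converge within {max_iter} iterations", last=w
        )
    lam = float(np.mean((a @ w) / w))
    return w, lam


def lambda_max_estimate(A: PairwiseMatrix, W) -> float:
    """Estimate lambda_max from a weight vector as ``(1/n) sum_i (AW)_i / W_i``.

    Exact when ``A`` is consistent and ``W`` its priority vector; used as a
    cross-check of the power-iteration eigenvalue.
    """
    W = np.asarray(W, dtype=float)
    if W.shape != (A.n,):
        raise AHPError(f"weight vector length {W.size} does not match order {A.n}")
    if np.any(W <= 0):
        raise AHPError("all weights must be strictly positive")
    return float(np.mean((A.values @ W) / W))


def consistency_index(lambda_max: float, n: int, tol: float = 1e-6) -> float:
    """CI = (lambda_max - n)/(n - 1), clipped at 0."""
    if n < 2:
        raise AHPError(f"consistency index needs order >= 2, got {n}")
    if lambda_max < n - tol:
        raise AHPError(f"lambda_max={lambda_max} below order {n}: not a reciprocal-matrix eigenvalue")
    return max(0.0, (lambda_max - n) / (n - 1))


def consistency_ratio(ci: float, n: int) -> ConsistencyReport:
    """CR = CI/RI with the < 0.10 acceptance rule; orders <= 2 are always consistent."""
    ri = random_index(n)
    if n <= 2 or ri == 0.0:
        return ConsistencyReport(lambda_max=float(n), ci=0.0, ri=ri, cr=0.0, acceptable=True)
    cr = ci / ri
    return ConsistencyReport(
        lambda_max=ci * (n - 1) + n, ci=ci, ri=ri, cr=cr, acceptable=cr < CR_THRESHOLD
    )


def consistency_report(A: PairwiseMatrix) -> ConsistencyReport:
    """Full consistency diagnostics of ``A`` via power iteration."""
    _, lam = principal_weights(A)
    ci = consistency_index(lam, A.n)
    return consistency_ratio(ci, A.n)


def _repair_candidates(a: np.ndarray, w: np.ndarray, saaty: bool):
    """Off-diagonal entries ranked by log-deviation from the eigen-ratio."""
    n = a.shape[0]
    devs = []
    for i in range(n):
        for j in range(i + 1, n):
            target = w[i] / w[j]
            devs.append((abs(np.log(a[i, j] * w[j] / w[i])), i, j, target))
    devs.sort(reverse=True)
    return devs


def repair_matrix(A: PairwiseMatrix, max_iter: int = 50) -> PairwiseMatrix:
    """Adjust ``A`` until ``CR < 0.10``.

    Iteratively replaces the entry deviating most (in log space) from the
    ratio implied by the current principal eigenvector.  If ``A`` was on
    the Saaty grid the replacement stays on the grid.  Already-acceptable
    input is returned unchanged.
    """
    report = consistency_report(A)
    if report.acceptable:
        return A
    saaty = A.is_saaty
    a = A.values.copy()
    for _ in range(max_iter):
        w, lam = principal_weights(PairwiseMatrix(a))
        report = consistency_ratio(consistency_index(lam, a.shape[0]), a.shape[0])
        if report.acceptable:
            return PairwiseMatrix(a)
        changed = False
        for dev, i, j, target in _repair_candidates(a, w, saaty):
            new = quantize_ratio(target) if saaty else target
            if not np.isclose(new, a[i, j]):
                a[i, j] = new
                a[j, i] = 1.0 / new
                changed = True
                break
        if not changed:
            # every entry already sits at its nearest admissible value:
            # rebuild wholesale from the eigenvector
            rebuilt = matrix_from_weights(w, quantize=saaty).values
            if np.allclose(rebuilt, a):
                break
            a = rebuilt
    report = consistency_report(PairwiseMatrix(a))
    if report.acceptable:
        return PairwiseMatrix(a)
    w, _ = principal_weights(PairwiseMatrix(a))
    worst = _repair_candidates(a, w, saaty)[0]
    raise ConvergenceError(
        f"could not reach CR < {CR_THRESHOLD} within {max_iter} rounds; "
        f"worst entry a[{worst[1]},{worst[2]}]={a[worst[1], worst[2]]:.4g} (CR={report.cr:.4f})",
        last=PairwiseMatrix(a),
    )
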