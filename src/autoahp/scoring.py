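"""Patient risk scores, the evaluation harness, matching and baselines.

A :class:`RiskScorecard` composes the hierarchy's leaf global weights with
per-leaf level scores: each leaf factor maps its (discrete) level to a
score in [0, 1] — the min-max-normalized empirical log-odds of the level —
and a patient's risk score is the weight-convex combination
``sum_leaf w_leaf * s_leaf(level)``, itself in [0, 1].

The metric harness reports AUC (Mann-Whitney rank statistic with midrank
ties), accuracy, and class-weighted precision/recall/F1; with weighted
averaging accuracy coincides with weighted recall.  Propensity matching is
greedy 1:1 nearest-neighbour without replacement within a caliper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .discretize import BinScheme, bin_assign
from .hierarchy import FactorHierarchy

__all__ = [
    "RiskScorecard",
    "MetricReport",
    "build_scorecard",
    "risk_score",
    "evaluate",
    "auc_score",
    "choose_threshold",
    "propensity_match",
    "BASELINE_METHODS",
    "run_baselines",
]


@dataclass
class MetricReport:
    """AUC, accuracy and class-weighted precision/recall/F1, all in [0, 1]."""

    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


@dataclass
class RiskScorecard:
    """Leaf global weights plus per-leaf level->score maps and a threshold."""

    weights: dict[str, float]  # leaf name -> global weight (sums to 1)
    level_scores: dict[str, dict] = field(default_factory=dict)  # leaf -> {level: score}
    variables: dict[str, str] = field(default_factory=dict)  # leaf -> cohort column
    majority_level: dict[str, object] = field(default_factory=dict)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"leaf weights sum to {total}, expected 1")
        for leaf, m in self.level_scores.items():
            for lv, s in m.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"score {s} for level {lv!r} of {leaf!r} outside [0, 1]")

    def to_json(self, path=None) -> str:
        d = {
            "weights": self.weights,
            "level_scores": {k: {str(lv): s for lv, s in m.items()}
                             for k, m in self.level_scores.items()},
            "variables": self.variables,
            "majority_level": {k: str(v) for k, v in self.majority_level.items()},
            "threshold": self.threshold,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _level_scores(levels: pd.Series, y: np.ndarray) -> tuple[dict, object]:
    """Min-max-normalized empirical log-odds per level (0 = lowest risk)."""
    tab = pd.DataFrame({"lv": levels, "y": y}).groupby("lv", observed=True)["y"].agg(["sum", "count"])
    lo = np.log((tab["sum"] + 0.5) / (tab["count"] - tab["sum"] + 0.5))
    majority = tab["count"].idxmax()
    if len(tab) == 1:
        warnings.warn("leaf with a single level; scoring it 0.5")
        return {tab.index[0]: 0.5}, majority
    rng = lo.max() - lo.min()
    if rng == 0:
        return {lv: 0.5 for lv in tab.index}, majority
    scores = (lo - lo.min()) / rng
    return dict(scores), majority


def build_scorecard(
    h: FactorHierarchy,
    data: pd.DataFrame,
    y,
    bins: dict[str, BinScheme] | None = None,
    threshold: float = 0.5,
) -> RiskScorecard:
    """Assemble a scorecard from a weighted hierarchy and training data.

    ``h`` must already carry local weights (call ``solve_weights`` /
    ``hierarchy_from_weights`` first).  Continuous leaves whose variable has
    a :class:`BinScheme` in ``bins`` are assigned bin levels before their
    level scores are estimated.
    """
    y = np.asarray(y)
    globals_, report = h.synthesize_global_weights()
    if not report.acceptable:
        raise ValueError(f"hierarchy fails the combination consistency test (CR={report.cr:.3f})")
    bins = bins or {}
    level_scores: dict[str, dict] = {}
    variables: dict[str, str] = {}
    majority: dict[str, object] = {}
    for leaf in h.leaves():
        var = leaf.variable or leaf.name
        if var not in data.columns:
            raise KeyError(f"leaf {leaf.name!r} references missing column {var!r}")
        col = data[var]
        if var in bins:
            col = pd.Series(bin_assign(bins[var], col.to_numpy()), index=col.index)
        level_scores[leaf.name], majority[leaf.name] = _level_scores(col, y)
        variables[leaf.name] = var
    return RiskScorecard(
        weights=globals_, level_scores=level_scores, variables=variables,
        majority_level=majority, threshold=threshold,
    )


def risk_score(record, card: RiskScorecard, bins: dict[str, BinScheme] | None = None):
    """Score one record (mapping) or a DataFrame of records, in [0, 1].

    Missing leaf values are imputed with the training-majority level (with
    a warning); an unseen level raises an error naming the leaf.
    """
    bins = bins or {}
    if isinstance(record, pd.DataFrame):
        return np.array([risk_score(row, card, bins) for _, row in record.iterrows()])
    total = 0.0
    for leaf, w in card.weights.items():
        var = card.variables.get(leaf, leaf)
        level = record.get(var) if hasattr(record, "get") else record[var]
        if level is None or (isinstance(level, float) and np.isnan(level)):
            warnings.warn(f"missing level for leaf {leaf!r}; imputing training majority")
            level = card.majority_level[leaf]
        elif var in bins:
            level = int(bin_assign(bins[var], level)[0])
        smap = card.level_scores[leaf]
        if level not in smap:
            # integer-coded levels may arrive as floats/strings
            for cast in (int, str, float):
                try:
                    if cast(level) in smap:
                        level = cast(level)
                        break
                except (TypeError, ValueError):
                    continue
            else:
                level = _nearest_level(level, smap, leaf)
        total += w * smap[level]
    return float(total)


def _nearest_level(level, smap: dict, leaf: str):
    """Clip an unseen numeric level to the nearest training level.

    Mirrors the end-bin clipping of binned variables; non-numeric unknown
    levels raise, naming the leaf.
    """
    try:
        lv = float(level)
        numeric = [(abs(float(k) - lv), k) for k in smap]
    except (TypeError, ValueError):
        raise KeyError(f"unknown level {level!r} for leaf {leaf!r}") from None
    return min(numeric)[1]


def auc_score(scores, labels) -> float:
    """AUC as the Mann-Whitney rank statistic with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined for single-class labels")
    r = rankdata(scores, method="average")
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Threshold the scores and report the five-column metric set.

    Precision/recall/F1 use class-weighted averaging, under which accuracy
    equals weighted recall; per-class F1 is the harmonic mean of that
    class's precision and recall before weighting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = auc_score(scores, labels)
    pred = (scores >= threshold).astype(int)
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels, pred, average="weighted", zero_division=0
    )
    return MetricReport(
        auc=auc,
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
    )


def choose_threshold(scores, labels) -> float:
    """Threshold maximizing weighted F1 on the given (training) split.

    Candidates are the observed score values (prediction rule ``score >=
    threshold``), so the chosen classification is invariant under strictly
    monotone score transforms; ties break to the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best_f1, best_t = -1.0, None
    for t in np.unique(scores):
        pred = (scores >= t).astype(int)
        _, _, f1, _ = precision_recall_fscore_support(
            labels, pred, average="weighted", zero_division=0
        )
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = float(f1), float(t)
    return best_t


def propensity_match(
    scores, group, caliper_sd: float = 0.2
) -> tuple[list[tuple[int, int]], float, float]:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    ``group`` flags the experimental arm (1) vs control (0); the caliper is
    ``caliper_sd * SD(scores)``.  Returns (pairs of positional indices,
    SMD before, SMD after).  An empty pair list (with a warning) means no
    match fell within the caliper.
    """
    scores = np.asarray(scores, dtype=float)
    group = np.asarray(group).astype(int)
    t_idx = np.flatnonzero(group == 1)
    c_idx = np.flatnonzero(group == 0)
    if t_idx.size == 0 or c_idx.size == 0:
        raise ValueError("both groups must be non-empty")

    def smd(ti, ci):
        a, b = scores[ti], scores[ci]
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2) if min(len(a), len(b)) > 1 else scores.std()
        return float(abs(a.mean() - b.mean()) / sd) if sd > 0 else 0.0

    before = smd(t_idx, c_idx)
    caliper = caliper_sd * scores.std()
    order = t_idx[np.argsort(scores[t_idx], kind="stable")[::-1]]
    ctrl = c_idx[np.argsort(scores[c_idx], kind="stable")]
    ctrl_scores = scores[ctrl]
    used = np.zeros(ctrl.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ti in order:
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        d = np.abs(ctrl_scores[free] - scores[ti])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            used[free[j]] = True
            pairs.append((int(ti), int(ctrl[free[j]])))
    if not pairs:
        warnings.warn("no control matched within the caliper")
        return [], before, float("nan")
    mt = np.array([p[0] for p in pairs])
    mc = np.array([p[1] for p in pairs])
    return pairs, before, smd(mt, mc)


def _baseline_builders(seed: int, n_features: int) -> dict:
    return {
        "svm": lambda: SVC(kernel="rbf", C=1.0, gamma=0.1, max_iter=100,
                           probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=9, metric="euclidean",
                                            weights="uniform"),
        "sgd": lambda: SGDClassifier(loss="log_loss", penalty="elasticnet", epsilon=0.1,
                                     max_iter=1000, random_state=seed),
        "logistic_regression": lambda: LogisticRegression(penalty="l2", C=1.0, max_iter=1000),
        "naive_bayes": lambda: GaussianNB(),
        "neural_network": lambda: MLPClassifier(hidden_layer_sizes=(100,), activation="relu",
                                                solver="adam", learning_rate_init=0.001,
                                                max_iter=200, random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=1000, max_features=min(5, n_features), random_state=seed),
    }


#: The seven comparison classifiers with their fixed hyper-parameters.
BASELINE_METHODS = ("svm", "knn", "sgd", "logistic_regression", "naive_bayes",
                    "neural_network", "random_forest")


def run_baselines(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    methods: tuple[str, ...] | list[str] = BASELINE_METHODS,
    seed: int = 0,
) -> dict[str, MetricReport]:
    """Fit each named baseline classifier and evaluate it with the shared harness.

    Probabilities are thresholded at the weighted-F1-optimal training
    threshold, mirroring the scorecard's classification rule.
    """
    X_train = pd.DataFrame(X_train)
    X_test = pd.DataFrame(X_test)
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    builders = _baseline_builders(seed, X_train.shape[1])
    unknown = [m for m in methods if m not in builders]
    if unknown:
        raise ValueError(f"unknown baseline methods: {unknown}; known: {sorted(builders)}")
    out: dict[str, MetricReport] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in methods:
            clf = builders[m]().fit(X_train.to_numpy(), y_train)
            p_train = clf.predict_proba(X_train.to_numpy())[:, 1]
            p_test = clf.predict_proba(X_test.to_numpy())[:, 1]
            out[m] = evaluate(p_test, y_test, threshold=choose_threshold(p_train, y_train))
    return out
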