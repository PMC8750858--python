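"""Scorecards, the metric harness, threshold choice, matching, baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import autoahp as aa
from autoahp.hierarchy import Node
from autoahp.scoring import RiskScorecard


def _card(weights, level_scores, variables=None):
    variables = variables or {k: k for k in weights}
    majority = {k: max(m, key=m.get) for k, m in level_scores.items()}
    return RiskScorecard(
        weights=weights, level_scores=level_scores, variables=variables,
        majority_level=majority,
    )


def _flat_hierarchy(names):
    root = Node("risk_score", children=[Node(n) for n in names])
    return aa.FactorHierarchy(root)


class TestBuildScorecard:
    def test_binary_leaf_equal_rates_scores_half(self, rng):
        h = _flat_hierarchy(["a", "b"])
        h.root.local_weights = np.array([0.5, 0.5])
        data = pd.DataFrame({"a": np.repeat([0, 1], 200), "b": np.tile([0, 1], 200)})
        y = np.tile([0, 0, 0, 1], 100)  # rate independent of a
        card = aa.build_scorecard(h, data, y)
        assert card.level_scores["a"][0] == pytest.approx(0.5, abs=0.15)
        assert sum(card.weights.values()) == pytest.approx(1.0)

    def test_three_level_log_odds_hand_oracle(self):
        # rates 0.1 / 0.2 / 0.4 at 1000 rows per level; smoothed log-odds
        # lo_k = log((ev+0.5)/(n-ev+0.5)) -> [-2.1924, -1.3844, -0.4052]
        # min-max normalized -> [0, 0.4521, 1]
        h = _flat_hierarchy(["x", "z"])
        h.root.local_weights = np.array([0.5, 0.5])
        lv = np.repeat([0, 1, 2], 1000)
        y = np.zeros(3000, dtype=int)
        y[:100] = 1
        y[1000:1200] = 1
        y[2000:2400] = 1
        data = pd.DataFrame({"x": lv, "z": np.zeros(3000, dtype=int)})
        with pytest.warns(UserWarning, match="single level"):
            card = aa.build_scorecard(h, data, y)
        lo = [np.log((e + 0.5) / (n - e + 0.5)) for e, n in [(100, 1000), (200, 1000), (400, 1000)]]
        expected = (np.array(lo) - lo[0]) / (lo[2] - lo[0])
        got = [card.level_scores["x"][k] for k in (0, 1, 2)]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got[1] == pytest.approx(0.4521, abs=5e-4)

    def test_single_level_leaf_scores_half_with_warning(self):
        h = _flat_hierarchy(["x", "z"])
        h.root.local_weights = np.array([0.7, 0.3])
        data = pd.DataFrame({"x": np.repeat([0, 1], 50), "z": np.zeros(100, dtype=int)})
        y = np.repeat([0, 1], 50)
        with pytest.warns(UserWarning, match="single level"):
            card = aa.build_scorecard(h, data, y)
        assert card.level_scores["z"] == {0: 0.5}


class TestRiskScore:
    card = _card(
        weights={"a": 0.5, "b": 0.3, "c": 0.2},
        level_scores={"a": {0: 0.0, 1: 1.0}, "b": {0: 0.0, 1: 1.0}, "c": {0: 0.0, 1: 0.5}},
    )

    def test_worked_example(self):
        # s = [1, 0, 0.5] with w = [0.5, 0.3, 0.2] -> 0.60
        assert aa.risk_score({"a": 1, "b": 0, "c": 1}, self.card) == pytest.approx(0.60)

    def test_extremes(self):
        assert aa.risk_score({"a": 0, "b": 0, "c": 0}, self.card) == 0.0
        assert aa.risk_score({"a": 1, "b": 1, "c": 1}, self.card) == pytest.approx(0.9)

    def test_monotone_in_any_leaf(self):
        base = aa.risk_score({"a": 0, "b": 0, "c": 0}, self.card)
        for leaf in ("a", "b", "c"):
            rec = {"a": 0, "b": 0, "c": 0, leaf: 1}
            assert aa.risk_score(rec, self.card) >= base

    def test_missing_level_imputed_with_warning(self):
        with pytest.warns(UserWarning, match="missing level"):
            s = aa.risk_score({"a": 1, "b": 1, "c": None}, self.card)
        assert 0.0 <= s <= 1.0

    def test_unknown_categorical_level_raises_naming_leaf(self):
        card = _card(
            weights={"a": 1.0},
            level_scores={"a": {"low": 0.0, "high": 1.0}},
        )
        with pytest.raises(KeyError, match="'a'"):
            aa.risk_score({"a": "unheard-of"}, card)

    def test_unseen_numeric_level_clips_to_nearest(self):
        assert aa.risk_score({"a": 9, "b": 0, "c": 0}, self.card) == pytest.approx(0.5)


class TestEvaluate:
    def test_perfect_separation_all_ones(self):
        scores = np.r_[np.full(50, 0.9), np.full(50, 0.1)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        rep = aa.evaluate(scores, labels, threshold=0.5)
        assert rep.auc == rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_random_scores_auc_near_half(self, rng):
        scores = rng.uniform(0, 1, 10_000)
        labels = np.tile([0, 1], 5000)
        assert aa.auc_score(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_auc_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 50))
            scores = rng.choice(np.linspace(0, 1, 7), n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = conc / (len(pos) * len(neg))
            assert aa.auc_score(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_accuracy_equals_weighted_recall(self, rng):
        scores = rng.uniform(0, 1, 500)
        labels = rng.binomial(1, 0.3, 500)
        rep = aa.evaluate(scores, labels, threshold=0.4)
        assert rep.accuracy == pytest.approx(rep.recall, abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            aa.evaluate([0.1, 0.9], [1, 1])

    @given(st.integers(0, 1000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 1, 100)
        labels = np.tile([0, 1], 50)
        a1 = aa.auc_score(scores, labels)
        a2 = aa.auc_score(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestChooseThreshold:
    def test_perfect_scores_lowest_separating_value(self):
        scores = np.r_[np.full(10, 0.2), np.full(10, 0.8)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        assert aa.choose_threshold(scores, labels) == pytest.approx(0.8)

    def test_agrees_with_grid_oracle(self, rng):
        from sklearn.metrics import f1_score

        for _ in range(30):
            scores = rng.uniform(0, 1, 60)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            t = aa.choose_threshold(scores, labels)
            best = max(
                f1_score(labels, scores >= c, average="weighted")
                for c in np.unique(scores)
            )
            got = f1_score(labels, scores >= t, average="weighted")
            assert got == pytest.approx(best, abs=1e-12)

    def test_monotone_transform_same_classification(self, rng):
        scores = rng.uniform(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        t1 = aa.choose_threshold(scores, labels)
        t2 = aa.choose_threshold(scores**3, labels)
        assert np.array_equal(scores >= t1, scores**3 >= t2)


class TestPropensityMatch:
    def test_identical_distributions_near_complete_matching(self, rng):
        scores = np.tile(rng.uniform(0, 1, 500), 2)
        group = np.r_[np.ones(500), np.zeros(500)]
        pairs, before, after = aa.propensity_match(scores, group)
        assert len(pairs) == 500
        assert after <= max(before, 0.01)

    def test_disjoint_ranges_no_pairs(self):
        scores = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
        group = np.r_[np.ones(20), np.zeros(20)]
        with pytest.warns(UserWarning, match="caliper"):
            pairs, _, after = aa.propensity_match(scores, group, caliper_sd=0.2)
        assert pairs == []

    def test_shifted_gaussian_post_match_smd_small(self, rng):
        # 500 treated vs a 3x control pool so the caliper can drop bad pairs
        scores = np.r_[rng.normal(0.3, 1, 500), rng.normal(0.0, 1, 1500)]
        group = np.r_[np.ones(500), np.zeros(1500)]
        pairs, before, after = aa.propensity_match(scores, group)
        assert before > 0.2
        assert after < 0.1

    def test_no_control_reused(self, rng):
        scores = rng.uniform(0, 1, 200)
        group = rng.integers(0, 2, 200)
        pairs, _, _ = aa.propensity_match(scores, group)
        controls = [c for _, c in pairs]
        assert len(controls) == len(set(controls))


class TestBaselines:
    def test_separable_data_every_method_perfect(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.tile([0, 1], n // 2)
        X = pd.DataFrame({"x": y * 2.0 + rng.normal(0, 0.01, n)})
        reports = aa.run_baselines(X, y, X, y, seed=0)
        assert set(reports) == set(aa.scoring.BASELINE_METHODS)
        for name, rep in reports.items():
            assert rep.f1 == pytest.approx(1.0), name

    def test_harness_identity_on_own_predictions(self):
        pred = np.tile([0, 1], 30).astype(float)
        rep = aa.evaluate(pred, pred, threshold=0.5)
        assert rep.precision == rep.recall == 1.0

    def test_unknown_method_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="unknown baseline"):
            aa.run_baselines(X, y, X, y, methods=["quantum_forest"])
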