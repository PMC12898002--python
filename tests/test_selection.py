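"""Three-stage selection, Shapley attribution, rank aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from tbs._treeshap import brute_force_shap, tree_shap_values
from tbs.selection import (BaggedPairClassifier, aggregate_ranks, rank_min,
                           rfe_select, shap_rank, three_stage_select,
                           univariate_filter)


def _toy_table(rng, n=40, p=12, informative=3, shift=2.0):
    y = np.repeat(["A", "B"], n // 2)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"MouthInspiration_F{i:02d}" for i in range(p)])
    for i in range(informative):
        X.iloc[:, i] += shift * (y == "B")
    return X, y


class TestTreeShapley:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 6))
        y = (X[:, 0] + 0.5 * X[:, 2] * X[:, 4] > 0).astype(int)
        for depth in (1, 3, None):
            tree = DecisionTreeClassifier(max_depth=depth,
                                          random_state=0).fit(X, y)
            phi, base = tree_shap_values(tree, X[:6])
            for i in range(6):
                assert np.allclose(phi[i], brute_force_shap(tree, X[i]),
                                   atol=1e-9)

    def test_additivity_to_model_margin(self):
        """Shapley efficiency: attributions plus base reproduce the ensemble
        score to 1e-6 on 20 random subjects."""
        rng = np.random.default_rng(1)
        X, y = _toy_table(rng, n=40, p=8)
        model = BaggedPairClassifier(n_bags=30, seed=0).fit(X.to_numpy(), y)
        model.feature_names_ = list(X.columns)
        _, phi, base = shap_rank(model, X.iloc[:20])
        scores = model.decision_scores(X.iloc[:20].to_numpy())
        assert np.max(np.abs(phi.sum(axis=1) + base - scores)) < 1e-6

    def test_unused_feature_gets_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        y = (X[:, 1] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        phi, _ = tree_shap_values(tree, X)
        used = {int(f) for f in tree.tree_.feature if f >= 0}
        for j in range(4):
            if j not in used:
                assert np.all(phi[:, j] == 0)

    def test_single_stump_full_margin(self):
        """A one-split tree assigns the entire margin deviation to the split
        feature (two-leaf closed form)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 3))
        y = (X[:, 0] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        phi, base = tree_shap_values(tree, X[:10])
        preds = tree.predict_proba(X[:10])[:, 1]
        assert np.allclose(phi[:, 0], preds - base, atol=1e-12)
        assert np.allclose(phi[:, 1:], 0)


class TestUnivariateFilter:
    def test_perfect_separator_scores_half_and_ranks_first(self):
        rng = np.random.default_rng(4)
        X, y = _toy_table(rng, n=30, p=6, informative=0)
        X["MouthInspiration_Perfect"] = (y == "B").astype(float)
        kept, scores = univariate_filter(X, y, keep=3)
        assert scores["MouthInspiration_Perfect"] == pytest.approx(0.5)
        assert kept.columns[0] == "MouthInspiration_Perfect"

    def test_null_feature_scores_near_zero(self):
        rng = np.random.default_rng(5)
        n = 2000
        X = pd.DataFrame({"f": rng.standard_normal(n)})
        y = np.repeat(["A", "B"], n // 2)
        _, scores = univariate_filter(X, y, keep=1)
        assert scores["f"] < 0.05

    def test_identical_columns_tie_broken_lexically(self):
        rng = np.random.default_rng(6)
        X, y = _toy_table(rng, n=20, p=2, informative=0)
        X["AAA_Dup"] = X.iloc[:, 0]
        X["ZZZ_Dup"] = X.iloc[:, 0]
        kept1, _ = univariate_filter(X, y, keep=3)
        kept2, _ = univariate_filter(X.copy(), y, keep=3)
        assert list(kept1.columns) == list(kept2.columns)
        dup_positions = [list(kept1.columns).index(c)
                         for c in ("AAA_Dup", "ZZZ_Dup")
                         if c in kept1.columns]
        assert dup_positions == sorted(dup_positions)

    def test_keep_larger_than_count_warns_and_keeps_all(self):
        rng = np.random.default_rng(7)
        X, y = _toy_table(rng, n=20, p=4)
        with pytest.warns(UserWarning):
            kept, _ = univariate_filter(X, y, keep=99)
        assert kept.shape[1] == 4


class TestRFE:
    def test_identity_when_target_equals_count(self):
        rng = np.random.default_rng(8)
        X, y = _toy_table(rng, n=30, p=5)
        out, trace = rfe_select(X, y, target_n=5, n_bags=10, seed=0)
        assert list(out.columns) == list(X.columns)
        assert trace.steps == []

    def test_trace_bookkeeping(self):
        rng = np.random.default_rng(9)
        X, y = _toy_table(rng, n=30, p=20)
        out, trace = rfe_select(X, y, target_n=6, n_bags=10, seed=0)
        assert out.shape[1] == 6
        assert sum(len(s) for s in trace.steps) == 20 - 6
        assert set(trace.kept) == set(out.columns)

    def test_target_exceeding_count_raises(self):
        rng = np.random.default_rng(10)
        X, y = _toy_table(rng, n=20, p=4)
        with pytest.raises(ValueError):
            rfe_select(X, y, target_n=10)


class TestThreeStage:
    def test_planted_feature_recovery(self):
        """Pipeline recovers planted informative features among pure noise
        with probability > 0.8 (10 seeds, 5 planted in 55)."""
        recovered, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = _toy_table(rng, n=40, p=55, informative=5, shift=1.5)
            final, _ = three_stage_select(X, y, keep=200, target_n=5,
                                          step=0.1, seed=seed, n_bags=50)
            recovered += sum(1 for c in final.columns if int(c[-2:]) < 5)
            total += 5
        assert recovered / total > 0.8

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        X, y = _toy_table(rng, n=30, p=25)
        f1, _ = three_stage_select(X, y, keep=20, target_n=5, seed=3,
                                   n_bags=15)
        f2, _ = three_stage_select(X.copy(), y, keep=20, target_n=5, seed=3,
                                   n_bags=15)
        assert list(f1.columns) == list(f2.columns)


class TestRankAggregation:
    @pytest.mark.parametrize("corr,shap,expected",
                             [(1, 2, 1.5), (3, 2, 2.5), (4, 4, 4.0)])
    def test_arithmetic_mean(self, corr, shap, expected):
        assert aggregate_ranks(corr, shap) == expected

    def test_non_positive_rank_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ranks(0, 2)

    def test_minimum_rank_tie_convention(self):
        s = pd.Series({"a": 3.0, "b": 3.0, "c": 1.0})
        r = rank_min(s)  # larger is better
        assert r["a"] == r["b"] == 1 and r["c"] == 3


class TestBaggedClassifier:
    def test_separable_training_auc_is_one(self):
        from tbs.evaluation import auc

        rng = np.random.default_rng(12)
        X, y = _toy_table(rng, n=30, p=4, informative=2, shift=6.0)
        m = BaggedPairClassifier(n_bags=25, seed=0).fit(X.to_numpy(), y)
        assert auc(m.decision_scores(X.to_numpy()), y) == 1.0

    def test_permuted_labels_give_null_auc(self):
        from tbs.evaluation import auc

        rng = np.random.default_rng(13)
        n = 200
        X = rng.standard_normal((n, 10))
        y_perm = rng.permutation(np.repeat(["A", "B"], n // 2))
        m = BaggedPairClassifier(n_bags=40, seed=1).fit(X[:150], y_perm[:150])
        test_auc = auc(m.decision_scores(X[150:]), y_perm[150:])
        assert abs(test_auc - 0.5) < 0.15

    def test_single_bag_equals_its_tree(self):
        rng = np.random.default_rng(14)
        X, y = _toy_table(rng, n=30, p=4)
        m = BaggedPairClassifier(n_bags=1, seed=2).fit(X.to_numpy(), y)
        scores = m.decision_scores(X.to_numpy())
        tree_scores = m.trees_[0].predict_proba(X.to_numpy())[:, 1]
        assert np.allclose(scores, tree_scores)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            BaggedPairClassifier(n_bags=2).fit(np.zeros((4, 2)),
                                               ["A", "A", "A", "A"])
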