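"""The tree ensemble, grouped CV, weighted AUC, and permutation testing."""

from __future__ import annotations

import numpy as np
import pytest

from acrminer.classifier import (
    AcrForest,
    family_grouped_cv,
    gini_impurity,
    permutation_pvalue,
    precision_recall,
    predict_scores,
    select_binary_threshold,
    train_forest,
    weighted_roc_auc,
)

from conftest import (
    oracle_permutation_pvalue_exact,
    oracle_weighted_auc,
)


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "fractions,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.8, 0.2), 0.32)],
    )
    def test_values(self, fractions, expected):
        assert gini_impurity(fractions) == pytest.approx(expected)

    def test_pure_node_is_exactly_zero(self):
        assert gini_impurity((1.0, 0.0)) == 0.0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0.5, 0.6))
        with pytest.raises(ValueError):
            gini_impurity((-0.1, 1.1))


def _separated(rng, n=60):
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


class TestTrainForest:
    def test_separable_data_trains_to_high_auc(self, rng):
        X, y = _separated(rng)
        forest = train_forest(X, y, n_trees=50, seed=0)
        auc = weighted_roc_auc(predict_scores(forest, X), y)
        assert auc >= 0.99

    def test_same_seed_identical_scores(self, rng):
        X, y = _separated(rng)
        s1 = predict_scores(train_forest(X, y, n_trees=20, seed=3), X)
        s2 = predict_scores(train_forest(X, y, n_trees=20, seed=3), X)
        assert (s1 == s2).all()

    def test_single_tree_degenerate_forest(self, rng):
        X, y = _separated(rng)
        forest = train_forest(X, y, n_trees=1, seed=0)
        assert predict_scores(forest, X).shape == (len(y),)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_forest(X, np.ones(10), seed=0)

    def test_nonpositive_weights_rejected(self, rng):
        X, y = _separated(rng)
        with pytest.raises(ValueError):
            train_forest(X, y, weights=np.zeros(len(y)), seed=0)

    def test_sklearn_estimator_api(self, rng):
        X, y = _separated(rng)
        forest = AcrForest(n_trees=10, random_state=0)
        assert forest.get_params()["n_trees"] == 10
        forest.set_params(n_trees=5).fit(X, y)
        assert forest.predict(X).shape == y.shape
        assert forest.predict_proba(X).shape == (len(y), 2)


class TestPredictScores:
    def test_scores_bounded(self, rng):
        X, y = _separated(rng)
        s = predict_scores(train_forest(X, y, n_trees=10, seed=1), X)
        assert ((0 <= s) & (s <= 1)).all()

    def test_training_positive_scores_near_one_in_pure_leaf_regime(self, rng):
        X, y = _separated(rng, n=40)
        forest = train_forest(X, y, n_trees=50, seed=2)
        assert predict_scores(forest, X[y == 1]).min() > 0.9

    def test_mean_of_trees_matches_manual_traversal(self, rng):
        """3-tree forest: scores equal the average, over trees, of the
        positive-class weight fraction in each sample's leaf (independent
        traversal of the fitted trees)."""
        X, y = _separated(rng, n=30)
        w = rng.uniform(0.5, 2.0, size=30)
        forest = train_forest(X, y, weights=w, n_trees=3, seed=4)
        pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        manual = np.zeros(len(y))
        for est in forest.forest_.estimators_:
            leaves = est.apply(X)
            for i, leaf in enumerate(leaves):
                val = est.tree_.value[leaf][0]
                manual[i] += val[pos_col] / val.sum()
        manual /= 3
        assert predict_scores(forest, X) == pytest.approx(manual)

    def test_feature_count_mismatch_rejected(self, rng):
        X, y = _separated(rng)
        forest = train_forest(X, y, n_trees=5, seed=0)
        with pytest.raises(ValueError, match="features"):
            forest.score_samples(X[:, :1])


class TestWeightedRocAuc:
    def test_perfect_separation(self):
        assert weighted_roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_labels(self):
        assert weighted_roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_tie_and_weights_match_pairwise_oracle(self):
        scores = [0.9, 0.5, 0.3, 0.5, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        weights = [2.0, 1.0, 0.5, 1.5, 1.0, 3.0]
        assert weighted_roc_auc(scores, labels, weights) == pytest.approx(
            oracle_weighted_auc(scores, labels, weights)
        )

    def test_random_cases_match_oracle(self, rng):
        """Concordance equivalence on random weighted sets up to n=200."""
        for _ in range(15):
            n = int(rng.integers(4, 201))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            w = rng.uniform(0.1, 3.0, size=n)
            assert weighted_roc_auc(s, y, w) == pytest.approx(
                oracle_weighted_auc(s, y, w)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            weighted_roc_auc([0.5, 0.6], [1, 1])

    def test_adding_dominant_positive_never_decreases_auc(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 40))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.random(n)
            base = weighted_roc_auc(s, y)
            s2 = np.append(s, s[y == 0].max() + 0.1)
            y2 = np.append(y, 1)
            assert weighted_roc_auc(s2, y2) >= base - 1e-12


def _family_data(rng, n_fam=6, per_fam=5, n_neg=30):
    X_pos = rng.normal(2.0, 1.0, size=(n_fam * per_fam, 2))
    X_neg = rng.normal(-2.0, 1.0, size=(n_neg, 2))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * len(X_pos) + [0] * n_neg)
    fams = np.array(
        [f"fam{i // per_fam}" for i in range(len(X_pos))] + [""] * n_neg
    )
    w = np.ones(len(y))
    return X, y, w, fams


class TestFamilyGroupedCv:
    def test_fifteen_aucs_for_5x3(self, rng):
        X, y, w, fams = _family_data(rng)
        res = family_grouped_cv(X, y, w, fams, seed=0, n_trees=15)
        assert len(res.aucs) == 15

    def test_folds_partition_families(self, rng):
        """With 6 families and 3 folds each fold holds exactly 2 families
        out, and no family is in both train and test."""
        X, y, w, fams = _family_data(rng, n_fam=6)
        res = family_grouped_cv(X, y, w, fams, n_reps=2, seed=1, n_trees=5)
        for rep in range(2):
            rep_assign = [a for a in res.fold_assignments if a["rep"] == rep]
            held_out = [set(a["test_families"]) for a in rep_assign]
            assert all(len(h) == 2 for h in held_out)
            assert set().union(*held_out) == {f"fam{i}" for i in range(6)}
            for a, b in zip(held_out, held_out[1:]):
                assert not a & b

    def test_too_few_families_rejected(self, rng):
        X, y, w, fams = _family_data(rng, n_fam=2)
        with pytest.raises(ValueError, match="families"):
            family_grouped_cv(X, y, w, fams, n_folds=3, seed=0)


class TestPermutationPvalue:
    def test_floor_when_observed_beats_all(self):
        """Perfectly separated scores cannot be beaten by any shuffle, so
        the p-value hits its floor 1/(N+1)."""
        scores = np.concatenate([np.full(20, 0.9), np.full(20, 0.1)])
        labels = np.array([1] * 20 + [0] * 20)
        p = permutation_pvalue(scores, labels, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_ceiling_when_observed_never_beats(self):
        """Constant scores: every permuted AUC equals the observed 0.5."""
        scores = np.full(20, 0.5)
        labels = np.array([1] * 10 + [0] * 10)
        assert permutation_pvalue(scores, labels, n_perm=200, seed=0) == 1.0

    def test_matches_exact_enumeration_on_four_examples(self):
        """Sampling approximates the exact all-orderings enumeration."""
        scores = [0.9, 0.7, 0.4, 0.1]
        labels = [1, 0, 1, 0]
        exact = oracle_permutation_pvalue_exact(scores, labels)
        n_perm = 4000
        p = permutation_pvalue(scores, labels, n_perm=n_perm, seed=1)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 4 * se + 2 / n_perm

    def test_null_distribution_centered_on_half(self, rng):
        """Mean of permuted-score AUCs is 0.5 within 3 SE."""
        labels = np.array([1] * 50 + [0] * 50)
        scores = rng.random(100)
        aucs = []
        g = np.random.default_rng(7)
        for _ in range(500):
            aucs.append(weighted_roc_auc(g.permutation(scores), labels))
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se


class TestSelectBinaryThreshold:
    def test_gap_separated_returns_gap_midpoint(self):
        scores = [0.8, 0.9, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        t = select_binary_threshold(scores, labels)
        assert t == pytest.approx(0.5)  # midpoint of the 0.2-0.8 gap

    def test_matches_exhaustive_grid_oracle(self, rng):
        """Best achievable weighted balanced accuracy over a dense
        threshold grid equals the one at the selected threshold."""
        from acrminer.classifier import _weighted_rates

        def bal_acc(scores, t, labels, w):
            tp, fp, fn, tn = _weighted_rates(scores, t, labels, w)
            tpr = tp / (tp + fn) if tp + fn else 0.0
            tnr = tn / (tn + fp) if tn + fp else 0.0
            return (tpr + tnr) / 2

        for _ in range(10):
            n = 30
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.choice(np.linspace(0, 1, 9), size=n)
            w = rng.uniform(0.2, 2.0, size=n)
            t = select_binary_threshold(s, y, w)
            best_grid = max(
                bal_acc(s, g, y, w) for g in np.linspace(-0.01, 1.01, 500)
            )
            assert bal_acc(s, t, y, w) == pytest.approx(best_grid)

    def test_threshold_reproduces_its_balanced_accuracy(self, rng):
        s = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        y[0], y[1] = 1, 0
        t1 = select_binary_threshold(s, y)
        t2 = select_binary_threshold(s, y)
        assert t1 == t2

    def test_accuracy_objective_option(self):
        s = [0.9, 0.8, 0.1]
        y = [1, 1, 0]
        assert 0.1 < select_binary_threshold(s, y, objective="accuracy") < 0.9
        with pytest.raises(ValueError):
            select_binary_threshold(s, y, objective="f1")


class TestPrecisionRecall:
    def test_all_correct(self):
        p, r = precision_recall([0.9, 0.8, 0.1], 0.5, [1, 1, 0])
        assert (p, r) == (1.0, 1.0)

    def test_threshold_zero_recall_one(self):
        _, r = precision_recall([0.9, 0.2, 0.1], 0.0, [1, 0, 1])
        assert r == 1.0

    def test_hand_computed_weighted_case(self):
        # predicted positive: a(1,w2), b(0,w1); missed positive: c(1,w3)
        scores = [0.9, 0.8, 0.3, 0.2, 0.6, 0.1]
        labels = [1, 0, 1, 0, 1, 0]
        weights = [2.0, 1.0, 3.0, 1.0, 1.0, 2.0]
        p, r = precision_recall(scores, 0.5, labels, weights)
        assert p == pytest.approx(3.0 / 4.0)  # (2+1)/(2+1+1)
        assert r == pytest.approx(3.0 / 6.0)  # (2+1)/(2+3+1)

    def test_no_predicted_positives_gives_nan_precision(self):
        p, r = precision_recall([0.1, 0.2], 0.9, [1, 0])
        assert np.isnan(p) and r == 0.0
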