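"""Weighted extremely-randomized-trees classifier and its evaluation.

The model is an ensemble of extremely randomized trees (default 1000)
trained on weighted examples: splits minimize weighted Gini impurity over
randomly drawn thresholds, and a candidate's score is the mean, over trees,
of the Acr weight fraction in the leaf it reaches.  Evaluation is by
family-grouped cross-validation (whole Acr families held out together),
weighted ROC-AUC, a permutation test on the scores, and balanced-accuracy
threshold selection for binary calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AcrForest",
    "CVResult",
    "gini_impurity",
    "train_forest",
    "predict_scores",
    "family_grouped_cv",
    "weighted_roc_auc",
    "permutation_pvalue",
    "select_binary_threshold",
    "precision_recall",
]


def gini_impurity(class_weight_fractions: Sequence[float], tol: float = 1e-9) -> float:
    """Gini impurity 1 - sum(p_i^2) of a node's class-weight fractions.

    Zero for a pure node; maximal (0.5 for two classes) when classes are
    evenly mixed.
    """
    p = np.asarray(class_weight_fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"fractions must sum to 1, got {p.sum()}")
    return float(1.0 - np.sum(p**2))


class AcrForest(BaseEstimator, ClassifierMixin):
    """Extremely-randomized-trees Acr classifier with sample weighting.

    A scikit-learn compatible estimator.  ``fit`` grows ``n_trees``
    extremely randomized trees on weighted examples; ``score_samples``
    returns the mean over trees of the positive-class weight fraction in
    each sample's leaf (a score in [0, 1]); ``predict`` thresholds that
    score at ``threshold``.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 1000).
    threshold : float
        Score cutoff for binary predictions (default 0.5; the pipeline
        typically learns one with :func:`select_binary_threshold`).
    max_features : str | int | float
        Features considered per split, as in the extremely-randomized-trees
        algorithm defaults ("sqrt").
    random_state : int | None
        Seed; mandatory for reproducible pipelines.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        threshold: float = 0.5,
        max_features="sqrt",
        random_state: Optional[int] = None,
        feature_names: Optional[Sequence[str]] = None,
    ) -> None:
        self.n_trees = n_trees
        self.threshold = threshold
        self.max_features = max_features
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            if (sample_weight <= 0).any():
                raise ValueError("sample weights must be positive")
        self.forest_ = ExtraTreesClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features=self.max_features,
            random_state=self.random_state,
        )
        self.forest_.fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.training_manifest_ = {
            "n_trees": self.n_trees,
            "max_features": self.max_features,
            "random_state": self.random_state,
            "n_examples": int(X.shape[0]),
            "feature_names": list(self.feature_names)
            if self.feature_names is not None
            else None,
        }
        return self

    def score_samples(self, X) -> np.ndarray:
        """Mean leaf positive-class weight fraction, in [0, 1]."""
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return self.forest_.predict_proba(X)[:, -1]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        scores = self.score_samples(X)
        pos = self.classes_[-1]
        neg = self.classes_[0]
        return np.where(scores >= self.threshold, pos, neg)


def train_forest(
    X, y, weights=None, n_trees: int = 1000, seed: Optional[int] = None, **kwargs
) -> AcrForest:
    """Convenience wrapper: fit an :class:`AcrForest` and return it."""
    forest = AcrForest(n_trees=n_trees, random_state=seed, **kwargs)
    return forest.fit(X, y, sample_weight=weights)


def predict_scores(forest: AcrForest, X) -> np.ndarray:
    """Scores in [0, 1]: mean over trees of the leaf Acr-weight fraction."""
    return forest.score_samples(X)


def weighted_roc_auc(scores, labels, weights=None) -> float:
    """Weighted ROC-AUC; ties between a positive and a negative earn half
    credit, so it equals the weighted pairwise concordance probability."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores, sample_weight=weights))


@dataclass
class CVResult:
    """Family-grouped cross-validation outcome."""

    aucs: list[float]
    fold_assignments: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def family_grouped_cv(
    X,
    y,
    weights,
    families,
    n_folds: int = 3,
    n_reps: int = 5,
    seed: Optional[int] = None,
    n_trees: int = 1000,
    **forest_kwargs,
) -> CVResult:
    """Cross-validation where folds partition Acr *families*, not proteins.

    Positives are assigned to folds family-by-family so a family never
    appears in both train and test; negatives are split randomly, anew in
    every repetition.  Returns ``n_reps * n_folds`` weighted AUCs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    weights = (
        np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    )
    families = np.asarray(families, dtype=object)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    fam_ids = sorted({families[i] for i in pos_idx})
    if len(fam_ids) < n_folds:
        raise ValueError(
            f"need >= {n_folds} Acr families, got {len(fam_ids)}"
        )
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    assignments: list[dict] = []
    for rep in range(n_reps):
        fam_perm = list(fam_ids)
        rng.shuffle(fam_perm)
        fam_folds = np.array_split(fam_perm, n_folds)
        neg_perm = neg_idx.copy()
        rng.shuffle(neg_perm)
        neg_folds = np.array_split(neg_perm, n_folds)
        for k in range(n_folds):
            test_fams = set(fam_folds[k])
            test_pos = np.array(
                [i for i in pos_idx if families[i] in test_fams], dtype=int
            )
            test_idx = np.concatenate([test_pos, neg_folds[k]])
            mask = np.ones(len(y), dtype=bool)
            mask[test_idx] = False
            train_idx = np.flatnonzero(mask)
            forest = AcrForest(
                n_trees=n_trees,
                random_state=int(rng.integers(2**31)),
                **forest_kwargs,
            ).fit(X[train_idx], y[train_idx], sample_weight=weights[train_idx])
            scores = forest.score_samples(X[test_idx])
            aucs.append(
                weighted_roc_auc(scores, y[test_idx], weights[test_idx])
            )
            assignments.append(
                {"rep": rep, "fold": k, "test_families": sorted(test_fams)}
            )
    return CVResult(aucs=aucs, fold_assignments=assignments)


def permutation_pvalue(
    scores,
    labels,
    weights=None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Permutation p-value of the weighted AUC.

    Model scores are shuffled against the fixed labels ``n_perm`` times;
    with n_p the number of permuted AUCs >= the observed AUC, the p-value
    is (1 + n_p) / (n_perm + 1) — ~0.001 at 1000 permutations when the
    observed AUC beats every permuted one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    observed = weighted_roc_auc(scores, labels, weights)
    n_p = 0
    for _ in range(n_perm):
        perm = rng.permutation(scores)
        if weighted_roc_auc(perm, labels, weights) >= observed:
            n_p += 1
    return (1 + n_p) / (n_perm + 1)


def _weighted_rates(scores, threshold, labels, weights):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    weights = (
        np.ones(len(labels)) if weights is None
        else np.asarray(weights, dtype=float)
    )
    pred = scores >= threshold
    tp = weights[(pred) & (labels == 1)].sum()
    fp = weights[(pred) & (labels == 0)].sum()
    fn = weights[(~pred) & (labels == 1)].sum()
    tn = weights[(~pred) & (labels == 0)].sum()
    return tp, fp, fn, tn


def select_binary_threshold(
    cv_scores,
    labels,
    weights=None,
    objective: str = "balanced_accuracy",
) -> float:
    """Score cutoff maximizing weighted balanced accuracy (or accuracy).

    Candidate thresholds are the midpoints between consecutive distinct
    score values plus the extremes, so a clean gap yields its midpoint.
    Ties go to the lowest threshold.
    """
    scores = np.asarray(cv_scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + np.finfo(float).eps]]
    )
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        tp, fp, fn, tn = _weighted_rates(scores, t, labels, weights)
        if objective == "balanced_accuracy":
            tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
            tnr = tn / (tn + fp) if tn + fp > 0 else 0.0
            v = (tpr + tnr) / 2.0
        elif objective == "accuracy":
            v = (tp + tn) / (tp + fp + fn + tn)
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if v > best_v:
            best_t, best_v = t, v
    return float(best_t)


def precision_recall(
    scores, threshold: float, labels, weights=None
) -> tuple[float, float]:
    """Weighted precision and recall of the call ``score >= threshold``.

    Precision is NaN when nothing is predicted positive.
    """
    tp, fp, fn, _tn = _weighted_rates(scores, threshold, labels, weights)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall
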