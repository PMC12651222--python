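"""Random-forest arm with majority voting and impurity importance.

T fully grown trees, each fit on a bootstrap sample with a random subset of
ceil(sqrt(F)) candidate features per split (Gini impurity). The predicted
label is the modal tree vote (ties break to the lexicographically smallest
class label) and the reported class probabilities are the tree-vote
fractions; feature importances are mean impurity decrease, normalised to sum
to one. The trees themselves come from scikit-learn.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier


class ForestModel:
    """Wrapper holding the fitted ensemble plus the class order used for votes."""

    def __init__(self, estimator: RandomForestClassifier):
        self.estimator = estimator
        self.classes_ = estimator.classes_

    @property
    def n_trees(self) -> int:
        return len(self.estimator.estimators_)


def train_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
                 seed: int = 0) -> ForestModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("random forest needs at least 2 classes present")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    max_features = max(1, int(np.ceil(np.sqrt(X.shape[1]))))
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=max_features,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return ForestModel(rf)


def predict_vote(model: ForestModel, X: np.ndarray):
    """Labels by majority vote and per-class vote fractions.

    Tie votes resolve to the lexicographically smallest class label
    (``classes_`` is sorted, and argmax returns the first maximum).
    """
    X = np.asarray(X, dtype=float)
    rf = model.estimator
    if X.shape[1] != rf.n_features_in_:
        raise ValueError(
            f"feature-count mismatch: model has {rf.n_features_in_}, got {X.shape[1]}"
        )
    counts = np.zeros((X.shape[0], len(model.classes_)))
    class_pos = {c: k for k, c in enumerate(model.classes_)}
    for tree in rf.estimators_:
        # individual trees are fit on encoded classes 0..K-1 in classes_ order
        votes = tree.predict(X).astype(int)
        counts[np.arange(X.shape[0]), votes] += 1
    fractions = counts / counts.sum(axis=1, keepdims=True)
    labels = model.classes_[np.argmax(fractions, axis=1)]
    return labels, fractions


def importance(model: ForestModel) -> np.ndarray:
    """Mean impurity decrease per feature, normalised to sum to 1."""
    imp = model.estimator.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp
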