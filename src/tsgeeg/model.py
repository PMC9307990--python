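"""Two-class random-forest classifier with updatable leaf posteriors.

The forest itself is scikit-learn's ``RandomForestClassifier`` with its
long-standing defaults (100 trees, Gini impurity, unlimited depth,
sqrt(n_features) split candidates, bootstrap resampling).  On top of the
frozen tree structure this module keeps an explicit per-leaf class-1
posterior, aggregated by soft voting (mean posterior across trees,
threshold 0.5, ties to class 0).

Making the posteriors explicit enables cheap transfer fine-tuning: given
labeled data from a new session, every leaf's posterior is replaced by the
empirical class-1 fraction of the new samples routed to it, and leaves that
receive no samples fall back to the uninformative posterior 0.5.  Split
structure is never modified.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, recall_score
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["LeafPosteriorForest", "balanced_accuracy", "fine_tune_posteriors",
           "ScoreReport", "score_report"]


class LeafPosteriorForest(ClassifierMixin, BaseEstimator):
    """Random forest over two classes with explicit leaf posteriors.

    Parameters mirror the scikit-learn forest defaults; ``random_state``
    controls bootstrap and split sampling.

    Attributes
    ----------
    forest_ : the fitted ``RandomForestClassifier`` (tree structure; never
        mutated after fit).
    leaf_posteriors_ : list of 1-D arrays, one per tree, mapping node id to
        the class-1 posterior of that node (only leaf ids are looked up).
    classes_ : the two class labels, sorted.
    fine_tuned_ : True when the posteriors were replaced by
        :meth:`fine_tune` (absent on a freshly fitted model).
    """

    def __init__(self, n_estimators: int = 100, criterion: str = "gini",
                 max_depth: int | None = None, max_features="sqrt",
                 bootstrap: bool = True, random_state: int | None = None,
                 n_jobs: int | None = None):
        self.n_estimators = n_estimators
        self.criterion = criterion
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"LeafPosteriorForest is strictly two-class; got {len(classes)} "
                "class(es) in y"
            )
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, criterion=self.criterion,
            max_depth=self.max_depth, max_features=self.max_features,
            bootstrap=self.bootstrap, random_state=self.random_state,
            n_jobs=self.n_jobs,
        )
        forest.fit(X, y)
        self.forest_ = forest
        self.classes_ = forest.classes_
        self.leaf_posteriors_ = [
            self._training_posteriors(tree) for tree in forest.estimators_
        ]
        return self

    @staticmethod
    def _training_posteriors(tree) -> np.ndarray:
        value = tree.tree_.value[:, 0, :]  # (n_nodes, 2), per-node class weights
        totals = value.sum(axis=1)
        safe = np.where(totals > 0, totals, 1.0)
        return value[:, 1] / safe

    def _mean_posterior(self, X: np.ndarray) -> np.ndarray:
        leaves = self.forest_.apply(X)  # (n_samples, n_trees)
        p = np.empty(leaves.shape, dtype=float)
        for t, post in enumerate(self.leaf_posteriors_):
            p[:, t] = post[leaves[:, t]]
        return p.mean(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = validate_data(self, X, reset=False)
        p1 = self._mean_posterior(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        # class 1 wins only on a strict majority posterior; ties go to class 0
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > 0.5).astype(int)]

    def fine_tune(self, X, y) -> "LeafPosteriorForest":
        """Return a copy whose leaf posteriors are re-estimated from (X, y).

        ``y`` may be single-class or empty; every leaf that receives no
        samples gets posterior 0.5.  The tree structure (shared with the
        source model, which stays unmodified) is untouched.
        """
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or (X.shape[0] and X.shape[1] != self.n_features_in_):
            raise ValueError(
                f"X must be (n, {self.n_features_in_}); got shape {X.shape}"
            )
        unknown = set(np.unique(y)) - set(self.classes_)
        if unknown:
            raise ValueError(f"labels {unknown} not among fitted classes")
        new = LeafPosteriorForest(**self.get_params())
        new.forest_ = self.forest_
        new.classes_ = self.classes_
        new.n_features_in_ = self.n_features_in_
        is_pos = (y == self.classes_[1]).astype(float)
        posteriors = []
        if X.shape[0]:
            leaves = self.forest_.apply(X)
        for t, tree in enumerate(self.forest_.estimators_):
            n_nodes = tree.tree_.node_count
            post = np.full(n_nodes, 0.5)
            if X.shape[0]:
                counts = np.bincount(leaves[:, t], minlength=n_nodes)
                pos = np.bincount(leaves[:, t], weights=is_pos, minlength=n_nodes)
                hit = counts > 0
                post[hit] = pos[hit] / counts[hit]
            posteriors.append(post)
        new.leaf_posteriors_ = posteriors
        new.fine_tuned_ = True
        return new


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls; undefined on a single-class y_true."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("balanced accuracy undefined: y_true has one class")
    return float(balanced_accuracy_score(y_true, y_pred))


def fine_tune_posteriors(model: LeafPosteriorForest, features, labels) -> LeafPosteriorForest:
    """Functional alias for :meth:`LeafPosteriorForest.fine_tune`."""
    return model.fine_tune(features, labels)


class ScoreReport(dict):
    """Dict of balanced/standard accuracy, per-class recalls and n_test."""


def score_report(y_true, y_pred) -> ScoreReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    recalls = recall_score(y_true, y_pred, labels=classes, average=None,
                           zero_division=0)
    return ScoreReport(
        balanced_accuracy=float(np.mean(recalls)),
        standard_accuracy=float(np.mean(y_true == y_pred)),
        per_class_recall={int(c): float(r) for c, r in zip(classes, recalls)},
        n_test=int(len(y_true)),
    )
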