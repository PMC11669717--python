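"""Balanced Random Forest classifier and its hyperparameter grid.

Treatment failure is the minority class (~30% of the cohort), so each tree
is grown on a class-balanced bootstrap: the same number of cases is drawn
from every class (the minority class count), with replacement when
``bootstrap=True`` and without (plain undersampling) otherwise.  The
estimator follows the scikit-learn API and drops into ``GridSearchCV``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = ["BalancedRandomForestClassifier", "BRF_PARAM_GRID", "grid_size", "tune_brf"]

# Hyperparameter search space for model tuning (2880 combinations).
BRF_PARAM_GRID = {
    "n_estimators": [50, 100, 200, 300],
    "max_depth": [2, 3, 5, 7],
    "min_samples_split": [2, 4, 6, 8, 10],
    "min_samples_leaf": [1, 2, 3],
    "max_features": ["auto", "sqrt", "log2"],
    "bootstrap": [True, False],
    "criterion": ["gini", "entropy"],
}


def grid_size(grid: dict = BRF_PARAM_GRID) -> int:
    """Number of hyperparameter combinations in a grid."""
    n = 1
    for v in grid.values():
        n *= len(v)
    return n


class BalancedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with a class-balanced bootstrap per tree.

    Parameters mirror :class:`sklearn.ensemble.RandomForestClassifier`;
    ``max_features='auto'`` is accepted as a synonym for ``'sqrt'`` (its
    historical meaning for classifiers).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: Optional[int] = None,
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        max_features="sqrt",
        bootstrap: bool = True,
        criterion: str = "gini",
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        class_idx = [np.flatnonzero(y == c) for c in self.classes_]
        n_min = min(len(ix) for ix in class_idx)
        max_features = "sqrt" if self.max_features == "auto" else self.max_features

        self.estimators_ = []
        importances = np.zeros(self.n_features_in_)
        for _ in range(int(self.n_estimators)):
            parts = []
            for ix in class_idx:
                if self.bootstrap:
                    parts.append(rng.choice(ix, size=n_min, replace=True))
                else:
                    parts.append(rng.permutation(ix)[:n_min])
            sample = np.concatenate(parts)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                max_features=max_features,
                criterion=self.criterion,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[sample], y[sample])
            self.estimators_.append(tree)
            importances += tree.feature_importances_
        self.feature_importances_ = importances / max(len(self.estimators_), 1)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            cols = np.searchsorted(self.classes_, tree.classes_)
            proba[:, cols] += p
        proba /= len(self.estimators_)
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def tune_brf(
    X,
    y,
    param_grid: Optional[dict] = None,
    seed: Optional[int] = None,
    cv_folds: int = 5,
    scoring: str = "roc_auc",
) -> GridSearchCV:
    """Grid-search a Balanced Random Forest with stratified k-fold CV.

    Returns the fitted :class:`GridSearchCV`; the AUC-maximizing point is
    refit on the full training set (``.best_estimator_``).
    """
    if param_grid is None:
        param_grid = BRF_PARAM_GRID
    y = np.asarray(y)
    counts = np.bincount(y.astype(int))
    if (counts[counts > 0] < cv_folds).any():
        raise ValueError("a class has fewer cases than CV folds")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        BalancedRandomForestClassifier(random_state=seed),
        param_grid,
        scoring=scoring,
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(np.asarray(X), y)
    return search
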