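"""Data split and two-stage feature selection.

Stage 1 ranks features by importance averaged over repeated 5-fold
cross-validation of four tree ensembles (Random Forest, Extra Trees,
AdaBoost, XGBoost); per-fit importances are min-max normalized to [0, 1]
before averaging so the four algorithms' scales are commensurate.

Stage 2 walks the ranking greedily and keeps a feature only if its absolute
Pearson correlation with every previously kept feature is at most ``r_max``
(default 0.5), stopping after ``k`` (default 17) features.

Both stages see training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import SelectorMixin
from sklearn.impute import SimpleImputer
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from xgboost import XGBClassifier

__all__ = [
    "split_train_test",
    "rank_importance",
    "select_nonredundant",
    "TwoStageFeatureSelector",
]

TRAIN_FRAC_DEFAULT = 0.84
R_MAX_DEFAULT = 0.5
K_DEFAULT = 17


def split_train_test(
    table: pd.DataFrame,
    labels: Sequence[int],
    train_frac: float = TRAIN_FRAC_DEFAULT,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified train/test split preserving the failure ratio.

    The test set holds ``floor(N * (1 - train_frac))`` cases (a 179-case
    cohort at the default 84% yields 151 train / 28 test); strata follow the
    binary failure label.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels must cover all table rows")
    for c in np.unique(labels):
        if (labels == c).sum() < 2:
            raise ValueError(f"stratum {c} has fewer than 2 cases")
    n_test = int(np.floor(len(table) * (1.0 - train_frac)))
    n_test = max(n_test, 2)
    idx = np.arange(len(table))
    tr, te = train_test_split(
        idx, test_size=n_test, stratify=labels, random_state=seed, shuffle=True
    )
    tr, te = np.sort(tr), np.sort(te)
    return table.iloc[tr], table.iloc[te], labels[tr], labels[te]


def _default_algorithms(seed: Optional[int]) -> Dict[str, BaseEstimator]:
    return {
        "RandomForest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "ExtraTrees": ExtraTreesClassifier(n_estimators=100, random_state=seed),
        "AdaBoost": AdaBoostClassifier(n_estimators=50, random_state=seed),
        "XGBoost": XGBClassifier(
            n_estimators=100,
            max_depth=3,
            eval_metric="logloss",
            random_state=seed if seed is not None else 0,
            verbosity=0,
        ),
    }


def rank_importance(
    train: pd.DataFrame,
    labels: Sequence[int],
    algorithms: Optional[Dict[str, BaseEstimator]] = None,
    folds: int = 5,
    repeats: int = 10,
    seed: Optional[int] = None,
    normalize: bool = True,
) -> pd.Series:
    """Mean feature-importance score across (algorithm x repeat x fold).

    Each fit's native importances are min-max normalized to [0, 1] (set
    ``normalize=False`` for raw averaging); the final score is the mean over
    all fits.  Returned as a descending Series; ties break lexicographically
    by feature id so the ranking is total and deterministic.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank importance")
    X = train.to_numpy(dtype=float)
    imputer = SimpleImputer(strategy="median")
    algos = algorithms if algorithms is not None else _default_algorithms(seed)
    rkf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(rkf.split(X, y))

    total = np.zeros(X.shape[1])
    n_fits = 0
    for est in algos.values():
        for tr_idx, _ in splits:
            Xi = imputer.fit_transform(X[tr_idx])
            model = clone(est)
            model.fit(Xi, y[tr_idx])
            imp = np.asarray(model.feature_importances_, dtype=float)
            if normalize:
                rng = np.ptp(imp)
                imp = (imp - imp.min()) / rng if rng > 0 else np.zeros_like(imp)
            total += imp
            n_fits += 1
    scores = pd.Series(total / n_fits, index=train.columns, name="importance")
    order = sorted(scores.index, key=lambda c: (-scores[c], c))
    return scores.loc[order]


def select_nonredundant(
    ranking: pd.Series,
    train: pd.DataFrame,
    r_max: float = R_MAX_DEFAULT,
    k: int = K_DEFAULT,
) -> List[str]:
    """Greedy non-redundancy filter over a descending importance ranking.

    The top-ranked feature is kept automatically; each next feature is kept
    iff its |Pearson r| with every kept feature is at most ``r_max``, until
    ``k`` features are kept.  If fewer than ``k`` survive, all survivors are
    returned with a warning.  Constant columns (undefined correlation) are
    treated as uncorrelated.
    """
    missing = set(ranking.index) - set(train.columns)
    if missing:
        raise ValueError(f"ranking names absent from table: {sorted(missing)[:3]}")
    X = train[ranking.index].to_numpy(dtype=float)
    # column-standardize once; constant or all-NaN columns get zero weight
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, nz] = X[:, nz] / sd[nz]
    n = X.shape[0]

    kept: List[int] = []
    for j in range(X.shape[1]):
        if len(kept) >= k:
            break
        if kept:
            r = np.abs(Xs[:, kept].T @ Xs[:, j]) / n
            if (r > r_max).any():
                continue
        kept.append(j)
    if len(kept) < k:
        warnings.warn(
            f"only {len(kept)} non-redundant features available (requested {k})"
        )
    return [ranking.index[j] for j in kept]


class TwoStageFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn transformer wrapping importance ranking + redundancy filter.

    ``fit`` ranks columns by cross-validated ensemble importance, then
    applies the greedy |Pearson r| <= ``r_max`` filter; ``transform`` keeps
    the selected columns.  Designed for DataFrame or array input.
    """

    def __init__(
        self,
        k: int = K_DEFAULT,
        r_max: float = R_MAX_DEFAULT,
        folds: int = 5,
        repeats: int = 10,
        random_state: Optional[int] = None,
    ):
        self.k = k
        self.r_max = r_max
        self.folds = folds
        self.repeats = repeats
        self.random_state = random_state

    def fit(self, X, y):
        df = X.copy() if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        df.columns = [str(c) for c in df.columns]
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.ranking_ = rank_importance(
            df, y, folds=self.folds, repeats=self.repeats, seed=self.random_state
        )
        self.selected_features_ = select_nonredundant(
            self.ranking_, df, r_max=self.r_max, k=self.k
        )
        self.support_ = np.isin(df.columns, self.selected_features_)
        return self

    def _get_support_mask(self):
        return self.support_
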