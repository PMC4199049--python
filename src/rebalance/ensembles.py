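"""Tree ensembles on the Gini engine: random forest and gradient boosting.

Both are re-implementations on :mod:`rebalance._engine`, not wrappers
around an external library.  The forest grows unpruned trees on bootstrap
resamples with a fresh random feature subset at every node; boosting
performs gradient descent on the Bernoulli deviance with depth-limited
least-squares trees and one-step Newton leaf updates, with shrinkage and
bag subsampling.  Defaults mirror the conventional defaults of the
classical R implementations: 500 trees / mtry = floor(sqrt(p)) /
node size 1 for the forest; 100 trees / depth 1 / shrinkage 0.1 /
bag fraction 0.5 / minimum terminal node weight 10 for boosting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _engine
from .tree import FeatureEncoder, _check_Xyw

__all__ = ["GiniForestClassifier", "GradientBoostedTreesClassifier",
           "fit_forest", "predict_forest", "fit_boost", "predict_boost"]


class GiniForestClassifier(ClassifierMixin, BaseEstimator):
    """Bagged Gini trees with per-node feature subsampling.

    Each of ``n_estimators`` trees is grown to purity (``minbucket`` 1,
    no pruning) on a bootstrap resample of n rows drawn with replacement,
    with selection probability proportional to case weight when the
    weighted training design is in use.  The forest score of a row is the
    mean over trees of the leaf case proportion.

    Attributes: ``trees_`` (engine roots), ``encoder_``,
    ``oob_indices_`` (per-tree out-of-bag row indices).
    """

    def __init__(self, n_estimators: int = 500, max_features="sqrt",
                 bootstrap: bool = True, minsplit: float = 2,
                 minbucket: float = 1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.minsplit = minsplit
        self.minbucket = minbucket
        self.random_state = random_state

    def _mtry(self, p: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(np.sqrt(p)))
        m = int(self.max_features)
        if not 1 <= m <= p:
            raise ValueError(f"max_features must be in [1, {p}]")
        return m

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        X, y, w = _check_Xyw(X, y, sample_weight)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(list(X.columns))
        self.encoder_ = FeatureEncoder().fit(X)
        cols = self.encoder_.transform(X, warn_unseen=False)
        n = len(X)
        mtry = self._mtry(X.shape[1])
        prob = None
        if not np.allclose(w, w[0]):
            prob = w / w.sum()
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.oob_indices_ = []
        for _ in range(self.n_estimators):
            if self.bootstrap:
                boot = rng.choice(n, size=n, replace=True, p=prob)
                oob = np.setdiff1d(np.arange(n), boot)
            else:
                boot = np.arange(n)
                oob = np.array([], dtype=int)
            feats = self.encoder_.feature_list(
                {k: v[boot] for k, v in cols.items()})
            root = _engine.grow(feats, y[boot], np.ones(n),
                                minsplit=self.minsplit,
                                minbucket=self.minbucket,
                                mtry=mtry, rng=rng)
            self.trees_.append(root)
            self.oob_indices_.append(oob)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.encoder_.transform(X)
        acc = np.zeros(len(X))
        for root in self.trees_:
            acc += _engine.predict_values(root, cols, len(X))
        p1 = acc / len(self.trees_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


class GradientBoostedTreesClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted trees for a binary outcome (Bernoulli deviance).

    Starting from the weighted-prevalence log-odds F0, each step fits a
    depth-limited least-squares tree to the negative gradient (residual
    y - p) on a random ``subsample`` fraction of rows, replaces each leaf
    value with the one-step Newton update
    sum(w * (y - p)) / sum(w * p * (1 - p)) over the in-bag leaf rows,
    and adds ``learning_rate`` times the increment.  Case weights enter
    both the gradient fit and the Newton updates.

    Attributes: ``f0_``, ``trees_`` (engine roots with Newton leaf
    values), ``train_deviance_`` (per-iteration mean weighted deviance).
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 1,
                 learning_rate: float = 0.1, subsample: float = 0.5,
                 min_leaf_weight: float = 10.0, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.min_leaf_weight = min_leaf_weight
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.n_estimators < 0:
            raise ValueError("n_estimators must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 < self.subsample <= 1.0:
            raise ValueError("subsample must be in (0, 1]")
        X, y, w = _check_Xyw(X, y, sample_weight)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(list(X.columns))
        self.encoder_ = FeatureEncoder().fit(X)
        cols = self.encoder_.transform(X, warn_unseen=False)
        n = len(X)
        p_bar = float((w * y).sum() / w.sum())
        self.f0_ = float(logit(np.clip(p_bar, 1e-12, 1 - 1e-12)))
        rng = np.random.default_rng(self.random_state)
        F = np.full(n, self.f0_)
        self.trees_ = []
        self.train_deviance_ = []
        n_bag = max(1, int(round(self.subsample * n)))
        # a leaf must be splittable into two legal children
        minsplit = max(2.0 * self.min_leaf_weight, 1e-9)
        for _ in range(self.n_estimators):
            p = expit(F)
            grad = y - p
            bag = (rng.choice(n, size=n_bag, replace=False)
                   if n_bag < n else np.arange(n))
            feats = self.encoder_.feature_list(
                {k: v[bag] for k, v in cols.items()})
            root = _engine.grow(feats, grad[bag], w[bag],
                                minsplit=minsplit,
                                minbucket=self.min_leaf_weight,
                                max_depth=self.max_depth)
            # Newton leaf updates from the in-bag rows of each leaf
            bag_cols = {k: v[bag] for k, v in cols.items()}
            bag_leaf = _engine.leaf_index(root, bag_cols, bag.size)
            leaves = root.leaves()
            for i, leaf in enumerate(leaves):
                rows = bag[bag_leaf == i]
                num = float((w[rows] * grad[rows]).sum())
                den = float((w[rows] * p[rows] * (1 - p[rows])).sum())
                leaf.value = num / den if den > 1e-12 else 0.0
            incr = _engine.predict_values(root, cols, n)
            F = F + self.learning_rate * incr
            self.trees_.append(root)
            p_new = expit(F)
            dev = _bernoulli_deviance(y, p_new, w)
            self.train_deviance_.append(dev)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.encoder_.transform(X)
        F = np.full(len(X), self.f0_)
        for root in self.trees_:
            F = F + self.learning_rate * _engine.predict_values(
                root, cols, len(X))
        return F

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def _bernoulli_deviance(y, p, w):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * (w * ll).sum() / w.sum())


# ---------------------------------------------------------------------------
# functional wrappers over cohort tables
# ---------------------------------------------------------------------------

def fit_forest(table: pd.DataFrame, B: int = 500, mtry=None,
               seed: int = 0, bootstrap: bool = True) -> GiniForestClassifier:
    from .cohort import split_xyw
    X, y, w = split_xyw(table)
    clf = GiniForestClassifier(
        n_estimators=B,
        max_features="sqrt" if mtry is None else mtry,
        bootstrap=bootstrap, random_state=seed)
    return clf.fit(X, y, sample_weight=w)


def predict_forest(model: GiniForestClassifier, table: pd.DataFrame):
    from .cohort import PREDICTORS
    cols = [c for c in PREDICTORS if c in table.columns]
    return model.predict_proba(table[cols])[:, 1]


def fit_boost(table: pd.DataFrame, M: int = 100, depth: int = 1,
              shrinkage: float = 0.1, bag_fraction: float = 0.5,
              seed: int = 0) -> GradientBoostedTreesClassifier:
    from .cohort import split_xyw
    X, y, w = split_xyw(table)
    clf = GradientBoostedTreesClassifier(
        n_estimators=M, max_depth=depth, learning_rate=shrinkage,
        subsample=bag_fraction, random_state=seed)
    return clf.fit(X, y, sample_weight=w)


def predict_boost(model: GradientBoostedTreesClassifier, table: pd.DataFrame):
    from .cohort import PREDICTORS
    cols = [c for c in PREDICTORS if c in table.columns]
    return model.predict_proba(table[cols])[:, 1]
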