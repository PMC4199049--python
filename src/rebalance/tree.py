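"""Gini-impurity CART: growing, cost-complexity pruning, 1-SE selection.

The classifier here is written from scratch on the engine in
:mod:`rebalance._engine`.  Growing maximises the decrease in weighted
Gini impurity; stopping and pruning use the weighted misclassification
risk under majority-vote labelling, normalised by the root risk — so a
complexity parameter ``cp`` keeps a subtree only while collapsing it
would raise the tree's risk by at least ``cp`` times the root risk per
leaf removed.  Growing first builds the largest tree permitted by
``minsplit``/``minbucket`` and then weakest-link-prunes it to ``cp``,
which is equivalent to rejecting under-performing splits during growth
but also yields the full pruning path for cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _engine
from ._engine import SplitRule, TreeNode  # re-exported for callers

__all__ = [
    "gini", "split_impurity", "best_split", "grow_tree",
    "cost_complexity_prune", "select_cp_1se", "predict_proba",
    "Tree", "GiniTreeClassifier", "PruneSequence",
]


# ---------------------------------------------------------------------------
# impurity primitives
# ---------------------------------------------------------------------------

def gini(w_case: float, w_control: float) -> float:
    """Gini impurity 1 - p1^2 - p2^2 of a two-class node.

    Arguments are class totals (counts or weights); the impurity is
    invariant to their common scale and symmetric in the two classes.
    """
    total = w_case + w_control
    if total <= 0:
        raise ValueError("empty class distribution")
    if w_case < 0 or w_control < 0:
        raise ValueError("class totals must be nonnegative")
    p1 = w_case / total
    p2 = w_control / total
    return 1.0 - p1 * p1 - p2 * p2


def split_impurity(left: tuple[float, float], right: tuple[float, float]) -> float:
    """Size-weighted average Gini impurity of two child nodes.

    ``left``/``right`` are (case, control) totals; the weights are the
    child totals over the parent total, so this is the quantity a split
    must drive below the parent's impurity to be worth anything.
    """
    wl = left[0] + left[1]
    wr = right[0] + right[1]
    if wl <= 0 or wr <= 0:
        raise ValueError("both children must be nonempty")
    total = wl + wr
    return (wl / total) * gini(*left) + (wr / total) * gini(*right)


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

class FeatureEncoder:
    """Maps a predictor DataFrame onto the engine's columnar arrays.

    Numeric columns become float arrays with NaN for missing; all other
    columns become integer level codes with -1 for missing.  Levels are
    frozen at fit time; unseen levels at prediction are routed like
    missing values, with a warning.
    """

    def fit(self, X: pd.DataFrame) -> "FeatureEncoder":
        self.meta_ = []
        for name in sorted(X.columns):
            col = X[name]
            if isinstance(col.dtype, pd.CategoricalDtype):
                self.meta_.append((name, "cat",
                                   [str(v) for v in col.cat.categories]))
            elif pd.api.types.is_numeric_dtype(col):
                self.meta_.append((name, "num", None))
            else:
                levels = sorted(str(v) for v in col.dropna().unique())
                self.meta_.append((name, "cat", levels))
        return self

    def transform(self, X: pd.DataFrame, warn_unseen: bool = True):
        """Returns {name: encoded array}; order follows ``meta_``."""
        cols = {}
        for name, kind, levels in self.meta_:
            if name not in X.columns:
                raise ValueError(f"missing predictor column {name!r}")
            if kind == "num":
                cols[name] = X[name].to_numpy(dtype=float)
            else:
                raw = X[name]
                cat = pd.Categorical(raw.astype(object), categories=levels)
                codes = cat.codes.astype(np.int64)
                if warn_unseen:
                    unseen = set(map(str, raw.dropna().unique())) - set(levels)
                    if unseen:
                        warnings.warn(
                            f"unseen levels {sorted(unseen)} in {name!r}; "
                            "routing like missing values")
                cols[name] = codes
        return cols

    def feature_list(self, cols):
        """Engine feature tuples (name, kind, column, n_levels)."""
        out = []
        for name, kind, levels in self.meta_:
            n_levels = len(levels) if levels is not None else 0
            out.append((name, kind, cols[name], n_levels))
        return out


# ---------------------------------------------------------------------------
# the Tree object
# ---------------------------------------------------------------------------

@dataclass
class PruneSequence:
    """Nested cost-complexity path: strictly increasing thresholds
    ``alphas`` (relative to the root risk), with per-threshold training
    risk, leaf counts and — after cross-validation — cv risk and SE."""

    alphas: list[float]
    risks: list[float]
    n_leaves: list[int]
    cv_risk: list[float] | None = None
    cv_se: list[float] | None = None


class Tree:
    """A grown (optionally pruned) classification tree plus its encoder.

    ``root`` nodes carry case/control weights; leaf values are weighted
    case proportions.  ``root_risk`` is min(total case weight, total
    control weight): the risk of the majority-vote root, the unit in
    which complexity thresholds are expressed.
    """

    def __init__(self, root: TreeNode, encoder: FeatureEncoder,
                 root_risk: float):
        self.root = root
        self.encoder = encoder
        self.root_risk = root_risk

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves

    def predict_proba(self, X: pd.DataFrame, cp: float | None = None) -> np.ndarray:
        """Per-row case probability (the leaf's weighted case proportion).

        ``cp`` optionally evaluates the subtree pruned at that relative
        threshold without materialising it.
        """
        cols = self.encoder.transform(X)
        alpha = None if cp is None else cp * self.root_risk
        return _engine.predict_values(self.root, cols, len(X), alpha=alpha)

    def prune(self, cp: float) -> "Tree":
        """New tree pruned at relative threshold ``cp``."""
        pruned = _engine.prune_to(self.root, cp * self.root_risk)
        return Tree(pruned, self.encoder, self.root_risk)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(n: TreeNode):
            d = {"n": n.n_rows, "w_case": n.wy, "w_control": n.w - n.wy,
                 "p_case": n.value}
            if not n.is_leaf:
                r = n.rule
                d["rule"] = {
                    "feature": r.feature, "kind": r.kind,
                    "threshold": r.threshold,
                    "left_levels": (sorted(r.left_levels)
                                    if r.left_levels is not None else None),
                    "missing_left": r.missing_left,
                }
                d["left"] = node_dict(n.left)
                d["right"] = node_dict(n.right)
            return d

        return {"root": node_dict(self.root), "root_risk": self.root_risk,
                "features": [{"name": n, "kind": k, "levels": lv}
                             for n, k, lv in self.encoder.meta_]}

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        enc = FeatureEncoder()
        enc.meta_ = [(f["name"], f["kind"], f["levels"])
                     for f in d["features"]]

        def build(nd):
            w = nd["w_case"] + nd["w_control"]
            node = TreeNode(w, nd["w_case"], nd["w_case"], nd["n"],
                            nd["p_case"])
            if "rule" in nd:
                r = nd["rule"]
                node.rule = SplitRule(
                    r["feature"], r["kind"], threshold=r["threshold"],
                    left_levels=(frozenset(r["left_levels"])
                                 if r["left_levels"] is not None else None),
                    missing_left=r["missing_left"])
                node.left = build(nd["left"])
                node.right = build(nd["right"])
            return node

        return cls(build(d["root"]), enc, d["root_risk"])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Tree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    # -- display ------------------------------------------------------------

    def render(self) -> str:
        """Plain-text tree: one line per node with rule, n and case %."""
        levels = {n: lv for n, _, lv in self.encoder.meta_ if lv is not None}
        lines = []

        def fmt_rule(rule: SplitRule, side: str) -> str:
            if rule.kind == "num":
                op = "<" if side == "left" else ">="
                return f"{rule.feature} {op} {rule.threshold:g}"
            lv = levels.get(rule.feature, [])
            sel = sorted(rule.left_levels)
            if side == "right":
                sel = [c for c in range(len(lv)) if c not in rule.left_levels]
            names = [lv[c] if 0 <= c < len(lv) else str(c) for c in sel]
            return f"{rule.feature} in {{{', '.join(names)}}}"

        def walk(node: TreeNode, label: str, depth: int):
            tag = "leaf" if node.is_leaf else "node"
            lines.append(f"{'  ' * depth}{label} [{tag}] n={node.n_rows} "
                         f"case%={100 * node.value:.1f}")
            if not node.is_leaf:
                walk(node.left, fmt_rule(node.rule, "left"), depth + 1)
                walk(node.right, fmt_rule(node.rule, "right"), depth + 1)

        walk(self.root, "root", 0)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GiniTreeClassifier(ClassifierMixin, BaseEstimator):
    """CART-style binary classifier grown by Gini impurity.

    Parameters
    ----------
    cp : float
        Complexity parameter: minimum decrease in relative risk per leaf
        a subtree must achieve to survive pruning.  Ignored when
        ``select='1se'``.
    minsplit : float
        Smallest node (total weight) eligible for splitting.
    minbucket : float or None
        Smallest permitted child (total weight); defaults to
        ``round(minsplit / 3)``.
    select : {'fixed', '1se'}
        ``'fixed'`` prunes at ``cp``; ``'1se'`` picks the complexity
        threshold by stratified cross-validation with the 1-SE rule.
    cv : int
        Cross-validation folds for ``select='1se'``.
    random_state : int
        Seed for the cross-validation fold deal.

    Attributes
    ----------
    tree_ : Tree
        The pruned tree used for prediction.
    full_tree_ : Tree
        The unpruned tree with its cost-complexity annotations.
    prune_path_ : PruneSequence
        Thresholds, training risks and (for 1-SE) cv risk estimates.
    cp_ : float
        The complexity threshold actually applied.
    """

    def __init__(self, cp: float = 0.01, minsplit: float = 20,
                 minbucket: float | None = None, select: str = "fixed",
                 cv: int = 10, random_state: int = 0):
        self.cp = cp
        self.minsplit = minsplit
        self.minbucket = minbucket
        self.select = select
        self.cv = cv
        self.random_state = random_state

    def _resolved_minbucket(self):
        return (round(self.minsplit / 3) if self.minbucket is None
                else self.minbucket)

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if self.cp < 0:
            raise ValueError("cp must be nonnegative")
        if self.select not in ("fixed", "1se"):
            raise ValueError("select must be 'fixed' or '1se'")
        X, y, w = _check_Xyw(X, y, sample_weight)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(list(X.columns))

        enc = FeatureEncoder().fit(X)
        cols = enc.transform(X, warn_unseen=False)
        feats = enc.feature_list(cols)
        minbucket = self._resolved_minbucket()
        if minbucket > self.minsplit:
            raise ValueError("minbucket must not exceed minsplit")
        root = _engine.grow(feats, y, w, minsplit=self.minsplit,
                            minbucket=minbucket)
        root_risk = min(root.wy, root.w - root.wy)
        alphas_abs = _engine.assign_prune_alphas(root)
        self.full_tree_ = Tree(root, enc, root_risk)
        self.prune_path_ = _path_from_alphas(root, root_risk, alphas_abs)

        if self.select == "1se":
            cp, cv_risk, cv_se = _cv_one_se(
                X, y, w, self.prune_path_.alphas, minsplit=self.minsplit,
                minbucket=minbucket, folds=self.cv, seed=self.random_state)
            self.prune_path_.cv_risk = cv_risk
            self.prune_path_.cv_se = cv_se
            self.cp_ = cp
        else:
            self.cp_ = self.cp
        self.tree_ = self.full_tree_.prune(self.cp_)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.tree_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def _check_Xyw(X, y, sample_weight):
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.size != len(X):
        raise ValueError("X and y length mismatch")
    if y.size == 0:
        raise ValueError("empty training table")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    w = (np.ones(y.size) if sample_weight is None
         else np.asarray(sample_weight, dtype=float))
    if (w <= 0).any():
        raise ValueError("sample weights must be positive")
    return X, y, w


def _path_from_alphas(root, root_risk, alphas_abs) -> PruneSequence:
    scale = root_risk if root_risk > 0 else 1.0
    # 0.0 is the full tree; a collapse threshold of exactly 0 (a split
    # with no risk improvement) supersedes it, so dedupe keeps the path
    # strictly increasing
    abs_list = [0.0] + [a for a in alphas_abs]
    abs_list = sorted({round(a, 15) for a in abs_list})
    rel, risks, leaves = [], [], []
    for a_abs in abs_list:
        r, nl = _engine.subtree_risk_leaves(root, a_abs)
        rel.append(a_abs / scale)
        risks.append(r / scale if root_risk > 0 else 0.0)
        leaves.append(nl)
    return PruneSequence(rel, risks, leaves)


def _stratified_folds(y, folds, rng):
    """Round-robin deal of shuffled cases and controls into folds."""
    assign = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _cv_one_se(X, y, w, alphas, *, minsplit, minbucket, folds, seed):
    """Cross-validated risk along the pruning path; 1-SE choice.

    Each path entry is evaluated at the geometric mean of its threshold
    and the next (the midpoint of the interval on which the subtree is
    optimal); fold trees are pruned at that value times their own root
    risk.  Fold risks are weighted misclassification of the held-out
    rows under majority-vote labels, normalised by the full-data root
    risk; the SE is the between-fold standard error.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes")
    enc = FeatureEncoder().fit(X)
    cols = enc.transform(X, warn_unseen=False)
    root_risk_full = min((w * y).sum(), (w * (1 - y)).sum())
    if root_risk_full <= 0:
        return alphas[-1], None, None

    # representative threshold per path entry
    betas = []
    for k, a in enumerate(alphas):
        if k + 1 < len(alphas):
            betas.append(float(np.sqrt(max(a, 0.0) * alphas[k + 1])))
        else:
            betas.append(a)

    assign = None
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        cand = _stratified_folds(y, folds, rng)
        ok = all(len(np.unique(y[cand != f])) == 2 for f in range(folds))
        if ok:
            assign = cand
            break
    if assign is None:
        raise ValueError("could not deal folds containing both classes")

    loss = np.zeros((len(betas), folds))
    for f in range(folds):
        tr = assign != f
        va = ~tr
        feats = enc.feature_list({k: v[tr] for k, v in cols.items()})
        root = _engine.grow(feats, y[tr], w[tr], minsplit=minsplit,
                            minbucket=minbucket)
        _engine.assign_prune_alphas(root)
        fold_root_risk = min(root.wy, root.w - root.wy)
        va_cols = {k: v[va] for k, v in cols.items()}
        for k, b in enumerate(betas):
            p = _engine.predict_values(root, va_cols, int(va.sum()),
                                       alpha=b * fold_root_risk)
            pred = (p > 0.5).astype(float)
            loss[k, f] = float((w[va] * (pred != y[va])).sum())

    cv_risk = loss.sum(axis=1) / root_risk_full
    per_fold = loss * folds / root_risk_full
    cv_se = per_fold.std(axis=1, ddof=1) / np.sqrt(folds)
    return one_se_select(alphas, cv_risk, cv_se), list(cv_risk), list(cv_se)


def one_se_select(alphas, cv_risk, cv_se) -> float:
    """The 1-SE rule: the largest threshold (simplest subtree) whose cv
    risk is within one standard error of the minimum."""
    cv_risk = np.asarray(cv_risk, dtype=float)
    cv_se = np.asarray(cv_se, dtype=float)
    i_min = int(np.argmin(cv_risk))
    limit = cv_risk[i_min] + cv_se[i_min]
    chosen = max(k for k in range(len(alphas)) if cv_risk[k] <= limit + 1e-12)
    return alphas[chosen]


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator / engine
# ---------------------------------------------------------------------------

def best_split(table: pd.DataFrame, minbucket: float = 1.0,
               outcome: str = "outcome", weight: str = "weight"):
    """Best single split of a cohort table; ``(rule, gini_decrease)`` or
    ``None``.  The decrease is parent Gini minus the size-weighted child
    Gini, in per-unit-weight (mean impurity) units."""
    X = table[[c for c in table.columns if c not in (outcome, weight)]]
    y = table[outcome].to_numpy(float)
    w = (table[weight].to_numpy(float) if weight in table.columns
         else np.ones(len(table)))
    enc = FeatureEncoder().fit(X)
    feats = enc.feature_list(enc.transform(X, warn_unseen=False))
    found = _engine.best_split_arrays(feats, y, w, np.arange(len(table)),
                                      minbucket)
    if found is None:
        return None
    rule, sse_dec = found
    return rule, 2.0 * sse_dec / w.sum()


def grow_tree(table: pd.DataFrame, cp: float = 0.01, minsplit: float = 20,
              minbucket: float | None = None) -> GiniTreeClassifier:
    """Fit a CART on a cohort table (outcome/weight columns recognised)."""
    from .cohort import split_xyw
    X, y, w = split_xyw(table)
    clf = GiniTreeClassifier(cp=cp, minsplit=minsplit, minbucket=minbucket)
    return clf.fit(X, y, sample_weight=w)


def cost_complexity_prune(clf: GiniTreeClassifier) -> PruneSequence:
    """The weakest-link pruning path of a fitted classifier."""
    return clf.prune_path_


def select_cp_1se(table: pd.DataFrame, folds: int = 10,
                  seed: int = 0, minsplit: float = 20,
                  minbucket: float | None = None) -> float:
    """Cross-validated 1-SE complexity threshold for a cohort table."""
    from .cohort import split_xyw
    X, y, w = split_xyw(table)
    clf = GiniTreeClassifier(select="1se", cv=folds, random_state=seed,
                             minsplit=minsplit, minbucket=minbucket)
    clf.fit(X, y, sample_weight=w)
    return clf.cp_


def predict_proba(clf: GiniTreeClassifier, table: pd.DataFrame) -> np.ndarray:
    """Per-row case probability for a cohort table."""
    from .cohort import PREDICTORS
    cols = [c for c in PREDICTORS if c in table.columns]
    return clf.predict_proba(table[cols])[:, 1]
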