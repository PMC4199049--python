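"""Low-level weighted binary recursive-partitioning engine.

One split-search engine serves both the two-class Gini tree and the
least-squares regression trees used inside gradient boosting.  For a 0/1
response ``y`` with case weights ``w`` the weighted sum of squared errors
of a node equals half its weighted Gini impurity::

    sum_i w_i (y_i - p)^2  =  W p (1 - p)  =  W * gini / 2,

so maximising the weighted-average Gini impurity decrease of a split is
algebraically identical to maximising the variance reduction of the 0/1
response.  The engine therefore grows every tree by weighted variance
reduction; the classification layer interprets node means as case
proportions and recovers impurities exactly.

Conventions shared by all trees built here:

* numeric splits send ``value < threshold`` left, where the threshold is
  the midpoint of the two straddling observed values;
* categorical splits send a subset of level codes left; only subsets that
  are contiguous when levels are ordered by weighted mean response are
  examined (optimal for two-class Gini and for least squares);
* rows with a missing value at a split follow the majority-weight side of
  that split, recorded on the rule as ``missing_left``;
* ``minsplit`` and ``minbucket`` are measured in total case weight, so a
  row with integer weight k behaves exactly like k replicated rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: categorical code for a missing level (and, at prediction time, a level
#: never seen during fitting — both are routed by ``missing_left``).
MISSING = -1

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SplitRule:
    """A binary split on one predictor.

    ``kind`` is ``"num"`` (go left iff value < ``threshold``) or ``"cat"``
    (go left iff the level code is in ``left_levels``).  ``missing_left``
    routes rows whose value is missing.
    """

    feature: str
    kind: str
    threshold: float | None = None
    left_levels: frozenset[int] | None = None
    missing_left: bool = True


class TreeNode:
    """Node of a grown tree.

    ``w`` is total weight, ``wy`` the weighted response sum (for a 0/1
    response: the total case weight), ``value`` the node prediction.
    ``crit`` is the cost-complexity threshold at which the node collapses
    (assigned by :func:`assign_prune_alphas`; ``None`` until then).
    """

    __slots__ = ("w", "wy", "wy2", "n_rows", "value", "rule", "left",
                 "right", "crit")

    def __init__(self, w, wy, wy2, n_rows, value):
        self.w = float(w)
        self.wy = float(wy)
        self.wy2 = float(wy2)
        self.n_rows = int(n_rows)
        self.value = float(value)
        self.rule = None
        self.left = None
        self.right = None
        self.crit = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    @property
    def w_case(self) -> float:
        """Total case weight (0/1 response only)."""
        return self.wy

    @property
    def w_control(self) -> float:
        return self.w - self.wy

    @property
    def risk(self) -> float:
        """Weighted misclassification risk under majority-vote labelling."""
        return min(self.wy, self.w - self.wy)

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _sse(w, wy, wy2):
    return wy2 - wy * wy / w if w > 0 else 0.0


def _num_candidates(v, yi, wi, minbucket, totals):
    """Best numeric cut for one feature; returns (sse_decrease, payload)."""
    w_tot, wy_tot, wy2_tot, sse_p = totals
    miss = np.isnan(v)
    vn = v[~miss]
    if vn.size < 2:
        return None
    wn = wi[~miss]
    yn = yi[~miss]
    order = np.argsort(vn, kind="stable")
    vs = vn[order]
    ws = wn[order]
    wys = (wn * yn)[order]
    wy2s = (wn * yn * yn)[order]
    cuts = np.nonzero(vs[1:] > vs[:-1])[0]
    if cuts.size == 0:
        return None
    cw = np.cumsum(ws)
    cwy = np.cumsum(wys)
    cwy2 = np.cumsum(wy2s)
    w_nm, wy_nm, wy2_nm = cw[-1], cwy[-1], cwy2[-1]
    wm = w_tot - w_nm
    wym = wy_tot - wy_nm
    wy2m = wy2_tot - wy2_nm

    wL = cw[cuts]
    wyL = cwy[cuts]
    wy2L = cwy2[cuts]
    wR = w_nm - wL
    wyR = wy_nm - wyL
    wy2R = wy2_nm - wy2L
    miss_left = wL >= wR
    if wm > 0:
        wL = wL + np.where(miss_left, wm, 0.0)
        wyL = wyL + np.where(miss_left, wym, 0.0)
        wy2L = wy2L + np.where(miss_left, wy2m, 0.0)
        wR = wR + np.where(miss_left, 0.0, wm)
        wyR = wyR + np.where(miss_left, 0.0, wym)
        wy2R = wy2R + np.where(miss_left, 0.0, wy2m)
    valid = (wL >= minbucket) & (wR >= minbucket)
    if not valid.any():
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        dec = sse_p - (wy2L - wyL**2 / wL) - (wy2R - wyR**2 / wR)
    dec = np.where(valid, dec, -np.inf)
    best = int(np.argmax(dec))  # first maximum -> smallest threshold
    if not np.isfinite(dec[best]):
        return None
    cut = cuts[best]
    thr = 0.5 * (vs[cut] + vs[cut + 1])
    return float(dec[best]), ("num", float(thr), bool(miss_left[best]))


def _cat_candidates(codes, yi, wi, minbucket, totals, n_levels):
    """Best contiguous-subset cut for one categorical feature."""
    w_tot, wy_tot, wy2_tot, sse_p = totals
    miss = codes < 0
    cn = codes[~miss]
    if cn.size == 0:
        return None
    wn = wi[~miss]
    yn = yi[~miss]
    w_lv = np.bincount(cn, weights=wn, minlength=n_levels)
    wy_lv = np.bincount(cn, weights=wn * yn, minlength=n_levels)
    wy2_lv = np.bincount(cn, weights=wn * yn * yn, minlength=n_levels)
    present = np.nonzero(w_lv > 0)[0]
    if present.size < 2:
        return None
    mean = wy_lv[present] / w_lv[present]
    # order by weighted mean response, ties by level code (determinism)
    order = present[np.lexsort((present, mean))]
    cw = np.cumsum(w_lv[order])
    cwy = np.cumsum(wy_lv[order])
    cwy2 = np.cumsum(wy2_lv[order])
    w_nm, wy_nm, wy2_nm = cw[-1], cwy[-1], cwy2[-1]
    wm = w_tot - w_nm
    wym = wy_tot - wy_nm
    wy2m = wy2_tot - wy2_nm

    k = np.arange(order.size - 1)
    wL = cw[k]
    wyL = cwy[k]
    wy2L = cwy2[k]
    wR = w_nm - wL
    wyR = wy_nm - wyL
    wy2R = wy2_nm - wy2L
    miss_left = wL >= wR
    if wm > 0:
        wL = wL + np.where(miss_left, wm, 0.0)
        wyL = wyL + np.where(miss_left, wym, 0.0)
        wy2L = wy2L + np.where(miss_left, wy2m, 0.0)
        wR = wR + np.where(miss_left, 0.0, wm)
        wyR = wyR + np.where(miss_left, 0.0, wym)
        wy2R = wy2R + np.where(miss_left, 0.0, wy2m)
    valid = (wL >= minbucket) & (wR >= minbucket)
    if not valid.any():
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        dec = sse_p - (wy2L - wyL**2 / wL) - (wy2R - wyR**2 / wR)
    dec = np.where(valid, dec, -np.inf)
    best = int(np.argmax(dec))  # first maximum -> smallest left subset
    if not np.isfinite(dec[best]):
        return None
    left = frozenset(int(c) for c in order[: best + 1])
    return float(dec[best]), ("cat", left, bool(miss_left[best]))


def best_split_arrays(features, y, w, idx, minbucket):
    """Exhaustive best split over ``features`` restricted to rows ``idx``.

    ``features`` is a list of ``(name, kind, column, n_levels)`` sorted by
    name; ties in SSE decrease keep the earlier candidate, i.e. the
    lexicographically smallest feature, then the smallest threshold or
    left subset.  Returns ``(rule, sse_decrease)`` or ``None``.
    """
    yi = y[idx]
    wi = w[idx]
    w_tot = float(wi.sum())
    wy_tot = float((wi * yi).sum())
    wy2_tot = float((wi * yi * yi).sum())
    sse_p = _sse(w_tot, wy_tot, wy2_tot)
    totals = (w_tot, wy_tot, wy2_tot, sse_p)

    best_dec = _TIE_TOL
    best_rule = None
    for name, kind, col, n_levels in features:
        v = col[idx]
        if kind == "num":
            cand = _num_candidates(v, yi, wi, minbucket, totals)
        else:
            cand = _cat_candidates(v, yi, wi, minbucket, totals, n_levels)
        if cand is None:
            continue
        dec, payload = cand
        if dec > best_dec + _TIE_TOL:
            best_dec = dec
            if payload[0] == "num":
                best_rule = SplitRule(name, "num", threshold=payload[1],
                                      missing_left=payload[2])
            else:
                best_rule = SplitRule(name, "cat", left_levels=payload[1],
                                      missing_left=payload[2])
    if best_rule is None:
        return None
    return best_rule, best_dec


def route_left_mask(rule: SplitRule, values: np.ndarray) -> np.ndarray:
    """Boolean mask of rows going to the left child under ``rule``."""
    if rule.kind == "num":
        miss = np.isnan(values)
        left = np.where(miss, rule.missing_left, values < rule.threshold)
    else:
        miss = values < 0
        left = np.isin(values, list(rule.left_levels))
        left = np.where(miss, rule.missing_left, left)
    return left.astype(bool)


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def grow(features, y, w, *, minsplit, minbucket, max_depth=None,
         mtry=None, rng=None):
    """Grow a tree by recursive partitioning (explicit stack, no pruning).

    ``minsplit``/``minbucket`` are weight totals.  ``mtry`` restricts the
    split search at every node to that many features sampled without
    replacement from ``rng`` (random-forest style).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise ValueError("cannot grow a tree on an empty table")
    if mtry is not None and rng is None:
        raise ValueError("mtry requires an rng")

    root_idx = np.arange(y.size)

    def make_node(idx):
        wi = w[idx]
        yi = y[idx]
        W = float(wi.sum())
        WY = float((wi * yi).sum())
        WY2 = float((wi * yi * yi).sum())
        return TreeNode(W, WY, WY2, idx.size, WY / W)

    root = make_node(root_idx)
    stack = [(root, root_idx, 0)]
    feat_map = {f[0]: f for f in features}
    while stack:
        node, idx, depth = stack.pop()
        if node.w < minsplit:
            continue
        if _sse(node.w, node.wy, node.wy2) <= 1e-12:
            continue
        if max_depth is not None and depth >= max_depth:
            continue
        if mtry is not None and mtry < len(features):
            pick = rng.choice(len(features), size=mtry, replace=False)
            feats = [features[i] for i in sorted(pick)]
        else:
            feats = features
        found = best_split_arrays(feats, y, w, idx, minbucket)
        if found is None:
            continue
        rule, _ = found
        col = feat_map[rule.feature][2]
        lmask = route_left_mask(rule, col[idx])
        lidx, ridx = idx[lmask], idx[~lmask]
        if lidx.size == 0 or ridx.size == 0:  # all weight on one side
            continue
        node.rule = rule
        node.left = make_node(lidx)
        node.right = make_node(ridx)
        stack.append((node.left, lidx, depth + 1))
        stack.append((node.right, ridx, depth + 1))
    return root


# ---------------------------------------------------------------------------
# cost-complexity pruning (classification risk = weighted misclassification)
# ---------------------------------------------------------------------------

def assign_prune_alphas(root: TreeNode) -> list[float]:
    """Weakest-link pruning: annotate every internal node with the
    complexity threshold ``crit`` at which it collapses.

    At threshold alpha the pruned tree treats every node with
    ``crit <= alpha`` as a leaf.  Returns the strictly increasing list of
    distinct collapse thresholds (empty for a root-only tree).  Risk is
    ``min(w_case, w_control)``, i.e. weighted misclassification under
    majority-vote labelling.
    """

    def internal_nodes(node, acc):
        if not node.is_leaf and node.crit is None:
            acc.append(node)
            internal_nodes(node.left, acc)
            internal_nodes(node.right, acc)
        return acc

    def subtree_stats(node):
        """(risk, leaves) of the subtree, honouring already-set crits."""
        if node.is_leaf or node.crit is not None:
            return node.risk, 1
        rl, ll = subtree_stats(node.left)
        rr, lr = subtree_stats(node.right)
        return rl + rr, ll + lr

    alphas = []
    while True:
        alive = internal_nodes(root, [])
        if not alive:
            break
        gs = []
        for t in alive:
            R, L = subtree_stats(t)
            g = (t.risk - R) / (L - 1) if L > 1 else np.inf
            gs.append(g)
        a = min(gs)
        eps = 1e-12 * (1.0 + abs(a))
        for t, g in zip(alive, gs):
            if g <= a + eps and t.crit is None:
                _collapse(t, a)
        alphas.append(a)
    # merge numerically equal thresholds
    out = []
    for a in alphas:
        if not out or a > out[-1] + 1e-12 * (1.0 + abs(a)):
            out.append(a)
    return out


def _collapse(node, a):
    """Mark ``node`` and every descendant internal node collapsed at a."""
    stack = [node]
    while stack:
        t = stack.pop()
        if not t.is_leaf and t.crit is None:
            t.crit = a
            stack.append(t.left)
            stack.append(t.right)


def effective_leaf(node: TreeNode, alpha: float) -> bool:
    """Whether ``node`` acts as a leaf in the subtree pruned at ``alpha``."""
    return node.is_leaf or (node.crit is not None
                            and node.crit <= alpha + 1e-12 * (1 + abs(alpha)))


def prune_to(root: TreeNode, alpha: float) -> TreeNode:
    """Deep-copied subtree with every node of ``crit <= alpha`` collapsed."""
    out = TreeNode(root.w, root.wy, root.wy2, root.n_rows, root.value)
    if not effective_leaf(root, alpha):
        out.rule = root.rule
        out.crit = root.crit
        out.left = prune_to(root.left, alpha)
        out.right = prune_to(root.right, alpha)
    return out


def subtree_risk_leaves(root: TreeNode, alpha: float) -> tuple[float, int]:
    """(risk, n_leaves) of the subtree pruned at ``alpha``."""
    if effective_leaf(root, alpha):
        return root.risk, 1
    rl, ll = subtree_risk_leaves(root.left, alpha)
    rr, lr = subtree_risk_leaves(root.right, alpha)
    return rl + rr, ll + lr


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_values(root: TreeNode, columns: dict[str, np.ndarray], n: int,
                   alpha: float | None = None) -> np.ndarray:
    """Route ``n`` rows through the tree; returns each row's leaf value.

    ``columns`` maps feature name -> encoded column (float with NaN for
    numeric, int codes with negatives for missing/unseen categorical).
    ``alpha`` optionally evaluates the subtree pruned at that threshold
    without materialising it.
    """
    out = np.empty(n, dtype=float)
    stack = [(root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf or (alpha is not None and effective_leaf(node, alpha)):
            out[idx] = node.value
            continue
        col = columns[node.rule.feature]
        lmask = route_left_mask(node.rule, col[idx])
        stack.append((node.left, idx[lmask]))
        stack.append((node.right, idx[~lmask]))
    return out


def leaf_index(root: TreeNode, columns: dict[str, np.ndarray],
               n: int) -> np.ndarray:
    """Index (into ``root.leaves()``) of the leaf each row lands in."""
    leaves = root.leaves()
    pos = {id(leaf): i for i, leaf in enumerate(leaves)}
    out = np.empty(n, dtype=int)
    stack = [(root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = pos[id(node)]
            continue
        col = columns[node.rule.feature]
        lmask = route_left_mask(node.rule, col[idx])
        stack.append((node.left, idx[lmask]))
        stack.append((node.right, idx[~lmask]))
    return out
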