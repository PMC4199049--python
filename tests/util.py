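"""Independent brute-force oracles used by the test suite.

These recompute tree quantities by naive enumeration, sharing nothing
with the engine's vectorised search except the stated conventions
(missing values follow the majority-weight side; children must each
carry at least ``minbucket`` weight).
"""

import itertools

import numpy as np
import pandas as pd

from rebalance.tree import gini, split_impurity


def _partition_decrease(y, w, left_mask):
    """Mean Gini impurity decrease of a concrete partition, or None."""
    wl1 = w[left_mask & (y == 1)].sum()
    wl2 = w[left_mask & (y == 0)].sum()
    wr1 = w[~left_mask & (y == 1)].sum()
    wr2 = w[~left_mask & (y == 0)].sum()
    if wl1 + wl2 <= 0 or wr1 + wr2 <= 0:
        return None
    parent = gini(wl1 + wr1, wl2 + wr2)
    return parent - split_impurity((wl1, wl2), (wr1, wr2))


def brute_force_best_split(table, minbucket=1.0, outcome="outcome",
                           weight="weight"):
    """Max Gini decrease over every threshold and every categorical
    subset, with missing rows sent to the majority-weight side."""
    y = table[outcome].to_numpy(int)
    w = (table[weight].to_numpy(float) if weight in table.columns
         else np.ones(len(table)))
    best = None
    for col in table.columns:
        if col in (outcome, weight):
            continue
        v = table[col]
        if pd.api.types.is_numeric_dtype(v) and not isinstance(
                v.dtype, pd.CategoricalDtype):
            x = v.to_numpy(float)
            miss = np.isnan(x)
            vals = np.unique(x[~miss])
            cuts = [(a + b) / 2 for a, b in zip(vals[:-1], vals[1:])]
            left_fns = [lambda x=x, t=t: x < t for t in cuts]
        else:
            levels = [lv for lv in v.dropna().unique()]
            left_fns = []
            for r in range(1, len(levels)):
                for sub in itertools.combinations(levels, r):
                    s = set(sub)
                    left_fns.append(
                        lambda v=v, s=s: v.isin(s).to_numpy())
            x = None
            miss = v.isna().to_numpy()
        for fn in left_fns:
            left = fn() & ~miss
            right = ~left & ~miss
            if w[left].sum() >= w[right].sum():
                left = left | miss
            else:
                right = right | miss
            if w[left].sum() < minbucket or w[right].sum() < minbucket:
                continue
            dec = _partition_decrease(y, w, left)
            if dec is not None and (best is None or dec > best):
                best = dec
    return best


def pairwise_auc(scores, labels):
    """AUC by direct enumeration of every case-control pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def all_subtree_options(node):
    """Every (risk, n_leaves) pair achievable by pruning the subtree."""
    opts = {(node.risk, 1)}
    if not node.is_leaf:
        for rl, ll in all_subtree_options(node.left):
            for rr, lr in all_subtree_options(node.right):
                opts.add((rl + rr, ll + lr))
    return opts
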