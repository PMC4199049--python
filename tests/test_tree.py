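"""CART engine: impurity arithmetic, split search, pruning, 1-SE, routing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rebalance as rb
from rebalance import _engine
from rebalance.cohort import split_xyw
from rebalance.tree import (GiniTreeClassifier, Tree, best_split, gini,
                            grow_tree, one_se_select, split_impurity)
from .conftest import make_imbalanced_table, random_mixed_table
from .util import all_subtree_options, brute_force_best_split


class TestGini:
    @pytest.mark.parametrize("w1,w2,expected", [
        (31, 2228, 0.0271),
        (997, 2228, 0.4272),
    ])
    def test_worked_node_values(self, w1, w2, expected):
        assert round(gini(w1, w2), 4) == expected

    def test_maximum_at_even_split(self):
        assert gini(10, 10) == pytest.approx(0.5)

    def test_pure_node_zero(self):
        assert gini(0, 57) == 0.0
        assert gini(57, 0) == 0.0

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini(0, 0)

    @given(w1=st.floats(0, 1e6), w2=st.floats(0, 1e6),
           c=st.floats(1e-3, 1e3))
    @settings(deadline=None, max_examples=200)
    def test_symmetric_and_scale_invariant(self, w1, w2, c):
        if w1 + w2 <= 0:
            return
        assert gini(w1, w2) == pytest.approx(gini(w2, w1))
        assert gini(c * w1, c * w2) == pytest.approx(gini(w1, w2))


class TestSplitImpurity:
    @pytest.mark.parametrize("left,right,expected", [
        ((13, 1718), (18, 510), 0.0268),
        ((431, 1718), (566, 510), 0.3801),
    ])
    def test_worked_split_values(self, left, right, expected):
        assert round(split_impurity(left, right), 4) == expected

    def test_pure_children_zero(self):
        assert split_impurity((5, 0), (0, 9)) == 0.0

    def test_empty_child_rejected(self):
        with pytest.raises(ValueError):
            split_impurity((0, 0), (3, 4))

    @given(st.tuples(*[st.integers(0, 500)] * 4))
    @settings(deadline=None, max_examples=200)
    def test_never_exceeds_parent_gini(self, counts):
        l1, l2, r1, r2 = counts
        if l1 + l2 == 0 or r1 + r2 == 0 or l1 + l2 + r1 + r2 == 0:
            return
        parent = gini(l1 + r1, l2 + r2)
        assert split_impurity((l1, l2), (r1, r2)) <= parent + 1e-12


class TestBestSplit:
    def test_worked_example_decrease(self, worked_node_table):
        rule, dec = best_split(worked_node_table, minbucket=1)
        assert rule.feature == "age" and rule.kind == "num"
        assert rule.threshold == pytest.approx(57.5)  # midpoint of 45, 70
        assert round(dec, 4) == pytest.approx(0.0271 - 0.0268)

    def test_oversampled_worked_example_amplified(self, worked_node_table):
        """Oversampling cases to 1:1 amplifies the same split's impurity
        decrease from 0.0003 to 0.0471."""
        # 13 -> 431 and 18 -> 566 case counts are not integer multiples,
        # so express the oversampled node through case weights
        t2 = worked_node_table.copy()
        t2.loc[(t2.outcome == 1) & (t2.age == 45), "weight"] = 431 / 13
        t2.loc[(t2.outcome == 1) & (t2.age == 70), "weight"] = 566 / 18
        rule, dec = best_split(t2, minbucket=1)
        assert rule.feature == "age"
        assert round(dec, 4) == pytest.approx(round(0.4272 - 0.3801, 4))

    def test_constant_predictor_gives_none(self):
        df = pd.DataFrame({"x": [1.0] * 20,
                           "outcome": [0, 1] * 10, "weight": 1.0})
        assert best_split(df, minbucket=1) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        table = random_mixed_table(n=80 + seed * 15, seed=seed,
                                   with_missing=(seed % 2 == 0))
        got = best_split(table, minbucket=2)
        want = brute_force_best_split(table, minbucket=2)
        assert got is not None and want is not None
        assert got[1] == pytest.approx(want, abs=1e-9)

    def test_minbucket_respected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=30),
                           "outcome": rng.integers(0, 2, 30),
                           "weight": 1.0})
        res = best_split(df, minbucket=10)
        if res is not None:
            rule, _ = res
            left = (df["x"] < rule.threshold).sum()
            assert 10 <= left <= 20


class TestGrowTree:
    def test_pure_table_single_leaf(self):
        df = pd.DataFrame({"x": np.arange(30.0), "outcome": 0, "weight": 1.0})
        df["outcome"] = 0
        clf = GiniTreeClassifier(cp=0.0, minsplit=2, minbucket=1)
        clf.fit(df[["x"]], df["outcome"])
        assert clf.tree_.n_leaves == 1

    def test_minsplit_20_blocks_19_rows(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=19),
                           "outcome": rng.integers(0, 2, 19)})
        clf = GiniTreeClassifier(cp=0.0, minsplit=20).fit(df[["x"]],
                                                          df["outcome"])
        assert clf.tree_.n_leaves == 1

    def test_cp_acceptance_rule_on_worked_nodes(self, worked_node_table):
        """Under the risk-scaled rule a split must cut weighted
        misclassification by cp x root risk.  The worked 'age < 60'
        split leaves every node control-majority (risk decrease 0), so
        cp=0.01 rejects it on the imbalanced node; on the 1:1
        oversampled node the children cut risk 997 -> 431+510, clearing
        the 0.01 x 997 bar, so the split survives."""
        t = worked_node_table
        clf = GiniTreeClassifier(cp=0.01, minsplit=20).fit(
            t[["age"]], t["outcome"])
        assert clf.tree_.n_leaves == 1  # risk decrease 0 < 0.01 * 31

        over = t.copy()
        over.loc[(over.outcome == 1) & (over.age == 45), "weight"] = 431 / 13
        over.loc[(over.outcome == 1) & (over.age == 70), "weight"] = 566 / 18
        clf2 = GiniTreeClassifier(cp=0.01, minsplit=20).fit(
            over[["age"]], over["outcome"],
            sample_weight=over["weight"])
        assert clf2.tree_.n_leaves == 2
        risk_dec = 997 - (431 + 510)
        assert risk_dec >= 0.01 * 997

    @pytest.mark.parametrize("seed", range(4))
    def test_every_internal_rule_is_brute_force_optimal(self, seed):
        table = random_mixed_table(n=150, seed=100 + seed)
        clf = GiniTreeClassifier(cp=0.0, minsplit=20, minbucket=7)
        clf.fit(table[[c for c in table if c not in ("outcome", "weight")]],
                table["outcome"])

        def walk(node, rows):
            if node.is_leaf or len(rows) == 0:
                return
            sub = table.iloc[rows]
            want = brute_force_best_split(sub, minbucket=7)
            got = best_split(sub, minbucket=7)
            assert got[1] == pytest.approx(want, abs=1e-9)
            cols = clf.full_tree_.encoder.transform(
                sub[[c for c in sub if c not in ("outcome", "weight")]])
            lmask = _engine.route_left_mask(
                node.rule, cols[node.rule.feature])
            walk(node.left, [rows[i] for i in range(len(rows)) if lmask[i]])
            walk(node.right,
                 [rows[i] for i in range(len(rows)) if not lmask[i]])

        walk(clf.full_tree_.root, list(range(len(table))))

    def test_integer_weight_equivalence(self):
        """Cases at weight k grow the identical tree, node for node, as
        physically k-replicated cases."""
        base = random_mixed_table(n=120, seed=42, p_case=0.15)
        k = 5
        weighted = base.copy()
        weighted.loc[weighted.outcome == 1, "weight"] = float(k)
        cases = base[base.outcome == 1]
        replicated = pd.concat([base] + [cases] * (k - 1),
                               ignore_index=True)

        def fit(t):
            X = t[[c for c in t if c not in ("outcome", "weight")]]
            return GiniTreeClassifier(cp=0.01, minsplit=20).fit(
                X, t["outcome"], sample_weight=t["weight"])

        a, b = fit(weighted), fit(replicated)

        def compare(na, nb):
            assert na.is_leaf == nb.is_leaf
            assert na.wy == pytest.approx(nb.wy)
            assert na.w == pytest.approx(nb.w)
            if not na.is_leaf:
                assert na.rule == nb.rule
                compare(na.left, nb.left)
                compare(na.right, nb.right)

        compare(a.tree_.root, b.tree_.root)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            GiniTreeClassifier().fit(pd.DataFrame({"x": []}), [])


class TestPruning:
    def test_single_leaf_sequence(self):
        df = pd.DataFrame({"x": np.arange(25.0), "outcome": 0})
        clf = GiniTreeClassifier(cp=0.0, minsplit=5, minbucket=1)
        clf.fit(df[["x"]], df["outcome"])
        assert clf.prune_path_.alphas == [0.0]

    def test_alphas_strictly_increase(self):
        table = random_mixed_table(n=200, seed=7)
        clf = GiniTreeClassifier(cp=0.0, minsplit=10, minbucket=3)
        clf.fit(table[[c for c in table if c not in ("outcome", "weight")]],
                table["outcome"])
        a = clf.prune_path_.alphas
        assert all(x < y for x, y in zip(a, a[1:]))
        assert clf.prune_path_.n_leaves[-1] == 1  # path ends at the root

    @pytest.mark.parametrize("seed", range(4))
    def test_weakest_link_matches_exhaustive_subtree_search(self, seed):
        """At every threshold the pruned tree minimises
        risk + alpha * leaves over ALL pruned subtrees."""
        table = random_mixed_table(n=50, seed=200 + seed)
        clf = GiniTreeClassifier(cp=0.0, minsplit=6, minbucket=2)
        clf.fit(table[[c for c in table if c not in ("outcome", "weight")]],
                table["outcome"])
        root = clf.full_tree_.root
        options = all_subtree_options(root)
        scale = clf.full_tree_.root_risk
        alphas_abs = [a * scale for a in clf.prune_path_.alphas]
        probe = list(alphas_abs)
        probe += [(x + y) / 2 for x, y in zip(alphas_abs, alphas_abs[1:])]
        probe.append((alphas_abs[-1] if alphas_abs else 0.0) + 1.0)
        for a in probe:
            risk, leaves = _engine.subtree_risk_leaves(root, a)
            ours = risk + a * leaves
            best = min(r + a * l for r, l in options)
            assert ours == pytest.approx(best, abs=1e-9)


class TestOneSE:
    def test_flat_risk_selects_largest_alpha(self):
        alphas = [0.0, 0.01, 0.05, 0.2]
        assert one_se_select(alphas, [1.0, 1.0, 1.0, 1.0],
                             [0.1] * 4) == 0.2

    def test_increasing_risk_with_tiny_se_selects_smallest(self):
        alphas = [0.0, 0.01, 0.05, 0.2]
        assert one_se_select(alphas, [0.5, 0.6, 0.7, 1.0],
                             [1e-9] * 4) == 0.0

    def test_no_signal_cohort_collapses_to_root(self):
        """With zero effects the cross-validated tree should be pruned
        back to the root in nearly every replicate."""
        cfg = rb.EffectConfig(age_per_year=0, bmi_per_unit=0,
                              pir_per_unit=0, education_per_level=0,
                              race_effects={}, target_prevalence=0.3)
        root_only = 0
        n_seeds = 20
        for s in range(n_seeds):
            t = rb.generate_cohort(400, cfg, seed=900 + s)
            X, y, w = split_xyw(t)
            if len(np.unique(y)) < 2:
                root_only += 1
                continue
            clf = GiniTreeClassifier(select="1se", cv=10, minsplit=20,
                                     random_state=s)
            clf.fit(X, y, sample_weight=w)
            if clf.tree_.n_leaves == 1:
                root_only += 1
        assert root_only >= 18

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": np.arange(40.0), "outcome": 0,
                           "weight": 1.0})
        clf = GiniTreeClassifier(select="1se")
        with pytest.raises(ValueError):
            clf.fit(df[["x"]], df["outcome"])


class TestPredict:
    def test_root_only_returns_prevalence(self):
        t = make_imbalanced_table(10, 90, seed=5)
        clf = grow_tree(t, cp=1.0)  # huge cp forces the root
        assert clf.tree_.n_leaves == 1
        p = clf.predict_proba(t[[c for c in t
                                 if c not in ("outcome", "weight")]])[:, 1]
        assert np.allclose(p, 0.1)

    def test_numeric_rule_semantics_below_training_range(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": np.r_[rng.normal(0, 1, 50),
                                      rng.normal(5, 1, 50)],
                           "outcome": np.r_[np.zeros(50), np.ones(50)]})
        clf = GiniTreeClassifier(cp=0.0, minsplit=10, minbucket=5)
        clf.fit(df[["x"]], df["outcome"])
        left_leaf_p = clf.predict_proba(pd.DataFrame({"x": [-100.0]}))[0, 1]
        assert left_leaf_p < 0.5  # follows the left (low-x, control) branch

    def test_missing_value_routes_majority_side(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(80), np.ones(20)],
                           "outcome": np.r_[np.zeros(80), np.ones(20)]})
        clf = GiniTreeClassifier(cp=0.0, minsplit=5, minbucket=2)
        clf.fit(df[["x"]], df["outcome"])
        rule = clf.tree_.root.rule
        assert rule.missing_left  # the control side holds 80% of weight
        p = clf.predict_proba(pd.DataFrame({"x": [np.nan]}))[0, 1]
        assert p == pytest.approx(0.0)

    def test_unseen_level_warns_and_routes(self):
        df = pd.DataFrame({
            "g": pd.Categorical(["a"] * 50 + ["b"] * 50),
            "outcome": [0] * 50 + [1] * 50})
        clf = GiniTreeClassifier(cp=0.0, minsplit=5, minbucket=2)
        clf.fit(df[["g"]], df["outcome"])
        new = pd.DataFrame({"g": pd.Categorical(["c"],
                                                categories=["a", "b", "c"])})
        with pytest.warns(UserWarning, match="unseen"):
            p = clf.predict_proba(new)
        assert 0.0 <= p[0, 1] <= 1.0

    def test_matches_reference_cart_on_clean_numeric_data(self):
        """On tie-free numeric data our unpruned tree and an independent
        reference CART (scikit-learn) grown with matched size limits
        yield the same leaf proportions."""
        from sklearn.tree import DecisionTreeClassifier
        rng = np.random.default_rng(77)
        n = 200
        X = pd.DataFrame({"a": rng.normal(size=n),
                          "b": rng.normal(size=n),
                          "c": rng.normal(size=n)})
        y = ((X["a"] + 0.5 * X["b"] + rng.normal(scale=0.8, size=n)) > 0
             ).astype(int)
        ours = GiniTreeClassifier(cp=0.0, minsplit=20, minbucket=7)
        ours.fit(X, y)
        p_ours = ours.full_tree_.predict_proba(X)
        ref = DecisionTreeClassifier(criterion="gini", min_samples_split=20,
                                     min_samples_leaf=7, random_state=0)
        ref.fit(X, y)
        p_ref = ref.predict_proba(X)[:, 1]
        agree = np.isclose(p_ours, p_ref, atol=1e-9).mean()
        assert agree >= 0.98  # divergence allowed only on split ties


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        table = random_mixed_table(n=150, seed=31, with_missing=True)
        X = table[[c for c in table if c not in ("outcome", "weight")]]
        clf = GiniTreeClassifier(cp=0.0, minsplit=15, minbucket=5)
        clf.fit(X, table["outcome"])
        path = tmp_path / "tree.json"
        clf.tree_.to_json(path)
        back = Tree.from_json(path)
        assert np.allclose(back.predict_proba(X),
                           clf.tree_.predict_proba(X))

    def test_render_mentions_rules_and_counts(self):
        t = make_imbalanced_table(40, 60, seed=8)
        clf = grow_tree(t, cp=0.0, minsplit=10, minbucket=4)
        text = clf.tree_.render()
        assert "root" in text and "n=" in text and "case%=" in text


def test_root_split_recovers_strong_predictors():
    """With strong BMI and age effects, the 1:1 undersampled root split
    lands on BMI or age in nearly all replicates."""
    cfg = rb.EffectConfig(bmi_per_unit=0.25, age_per_year=0.09)
    hits = 0
    n_seeds = 20
    for s in range(n_seeds):
        t = rb.generate_cohort(3264, cfg, seed=500 + s)
        if t.outcome.sum() < 2:
            continue
        un = rb.undersample(t, 1, seed=s)
        clf = grow_tree(un, cp=0.01)
        root = clf.tree_.root
        if not root.is_leaf and root.rule.feature in ("bmi", "age"):
            hits += 1
    assert hits >= 0.9 * n_seeds
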