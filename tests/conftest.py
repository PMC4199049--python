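"""Shared fixtures: small synthetic cohorts and the worked-example node."""

import numpy as np
import pandas as pd
import pytest

import rebalance as rb
from rebalance.cohort import (COLUMNS, EDUCATION_LEVELS, GENDER_LEVELS,
                              MARITAL_LEVELS, RACE_LEVELS)


def make_imbalanced_table(n_case=99, n_control=3165, seed=0):
    """Cohort with exactly the requested class counts (covariates drawn
    from the default marginals, outcome overwritten)."""
    n = n_case + n_control
    table = rb.generate_cohort(n, seed=seed)
    table = table.copy()
    table["outcome"] = 0
    rng = np.random.default_rng(seed + 1)
    case_rows = rng.choice(n, size=n_case, replace=False)
    table.iloc[case_rows, table.columns.get_loc("outcome")] = 1
    return table


def random_mixed_table(n, seed, n_num=2, n_cat=2, with_missing=False,
                       p_case=0.4):
    """Small random table with numeric + categorical predictors for
    oracle comparisons (ties made likely by rounding)."""
    rng = np.random.default_rng(seed)
    data = {}
    for j in range(n_num):
        data[f"num{j}"] = np.round(rng.normal(size=n), 1)
    for j in range(n_cat):
        k = rng.integers(3, 6)
        data[f"cat{j}"] = pd.Categorical.from_codes(
            rng.integers(0, k, size=n), [f"L{i}" for i in range(k)])
    df = pd.DataFrame(data)
    if with_missing:
        for j in range(n_num):
            df.loc[rng.random(n) < 0.1, f"num{j}"] = np.nan
    df["outcome"] = (rng.random(n) < p_case).astype(int)
    df["weight"] = 1.0
    return df


@pytest.fixture(scope="session")
def cohort_4677():
    return rb.generate_cohort(4677, seed=11)


@pytest.fixture(scope="session")
def imbalanced_99_3165():
    return make_imbalanced_table(99, 3165, seed=3)


@pytest.fixture
def worked_node_table():
    """Single-predictor table reproducing the worked impurity example:
    a node of 31 cases / 2228 controls where 'age < 60' yields children
    (13 cases, 1718 controls) and (18 cases, 510 controls)."""
    rows = []
    for age, outcome, count in [(45, 1, 13), (45, 0, 1718),
                                (70, 1, 18), (70, 0, 510)]:
        rows.extend([(age, outcome)] * count)
    df = pd.DataFrame(rows, columns=["age", "outcome"])
    df["weight"] = 1.0
    return df
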