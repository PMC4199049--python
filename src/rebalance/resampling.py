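"""Random over/undersampling and class weighting for imbalanced cohorts.

The training variants compared by the pipeline are: the table unchanged, a
class-weighted table, random oversampling of cases with replacement, and
random undersampling of controls without replacement, each at a target
case-to-control ratio of 1:r.  Resampling is always applied to the
training split only — never to held-out data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import child_seed

METHODS = ("none", "weight", "oversample", "undersample")


@dataclass(frozen=True)
class ResamplingPlan:
    """One training-variant recipe: method, 1:r target ratio, seed."""

    method: str
    ratio: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "none" and (self.ratio is None or self.ratio <= 0):
            raise ValueError("ratio must be a positive integer")

    @property
    def label(self) -> str:
        if self.method == "none":
            return "full"
        return f"{self.method} 1:{self.ratio}"


def _classes(table: pd.DataFrame):
    is_case = table["outcome"].to_numpy() == 1
    return table[is_case], table[~is_case]


def target_case_count(n_control: int, ratio: int) -> int:
    """Case count needed for a 1:``ratio`` case-to-control ratio.

    Fractional targets round up (ceiling), which is what reproduces the
    combined sizes 6330 / 4748 / 3957 from 3165 controls at ratios
    1, 2, 4.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if n_control < 0:
        raise ValueError("n_control must be nonnegative")
    return math.ceil(n_control / ratio)


def oversample(table: pd.DataFrame, ratio: int, seed: int = 0,
               include_originals: bool = False) -> pd.DataFrame:
    """Oversample cases with replacement to a 1:``ratio`` ratio.

    Controls pass through unchanged; the output is controls followed by
    the sampled cases, all with weight 1.  With ``include_originals`` each
    original case is kept once and only the remainder is drawn at random
    (off by default: plain uniform sampling with replacement).
    """
    cases, controls = _classes(table)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("oversample requires at least one case and control")
    target = target_case_count(len(controls), ratio)
    rng = np.random.default_rng(child_seed(seed, "oversample", ratio))
    if include_originals:
        if target < len(cases):
            raise ValueError("target below original case count with "
                             "include_originals")
        extra = rng.integers(0, len(cases), size=target - len(cases))
        pick = np.concatenate([np.arange(len(cases)), extra])
    else:
        pick = rng.integers(0, len(cases), size=target)
    sampled = cases.iloc[pick]
    out = pd.concat([controls, sampled], ignore_index=True)
    out["weight"] = 1.0
    return out


def undersample(table: pd.DataFrame, ratio: int, seed: int = 0) -> pd.DataFrame:
    """Undersample controls without replacement to a 1:``ratio`` ratio.

    All cases pass through; exactly ``ratio`` x n_case controls are drawn
    uniformly without replacement, with weight 1.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    cases, controls = _classes(table)
    n_keep = ratio * len(cases)
    if len(cases) == 0:
        raise ValueError("undersample requires at least one case")
    if len(controls) < n_keep:
        raise ValueError(
            f"too few controls ({len(controls)}) for ratio 1:{ratio} "
            f"with {len(cases)} cases")
    rng = np.random.default_rng(child_seed(seed, "undersample", ratio))
    pick = rng.choice(len(controls), size=n_keep, replace=False)
    kept = controls.iloc[np.sort(pick)]
    out = pd.concat([cases, kept], ignore_index=True)
    out["weight"] = 1.0
    return out


def class_weights(table: pd.DataFrame, ratio: int = 1) -> pd.DataFrame:
    """Reweight rows so total case weight : total control weight = 1:ratio.

    Controls keep weight 1 and every case receives
    ``n_control / (ratio * n_case)``; no rows are added or removed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    cases, controls = _classes(table)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("class weighting requires both classes")
    out = table.copy()
    w_case = len(controls) / (ratio * len(cases))
    out["weight"] = np.where(out["outcome"].to_numpy() == 1, w_case, 1.0)
    return out


def apply_plan(table: pd.DataFrame, plan: ResamplingPlan) -> pd.DataFrame:
    """Materialise one training variant."""
    if plan.method == "none":
        return table.copy()
    if plan.method == "weight":
        return class_weights(table, plan.ratio)
    if plan.method == "oversample":
        return oversample(table, plan.ratio, seed=plan.seed)
    return undersample(table, plan.ratio, seed=plan.seed)


def replication_plans(seed: int = 0) -> list[ResamplingPlan]:
    """The eight training variants of the reference experiment:
    full, weighted 1:1, over 1:1/1:2/1:4, under 1:1/1:2/1:4."""
    plans = [ResamplingPlan("none"), ResamplingPlan("weight", 1, seed)]
    for r in (1, 2, 4):
        plans.append(ResamplingPlan("oversample", r, seed))
    for r in (1, 2, 4):
        plans.append(ResamplingPlan("undersample", r, seed))
    return plans
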