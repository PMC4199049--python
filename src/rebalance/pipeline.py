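"""Experiment orchestration: the resampling x model grid.

One experiment takes a cohort (generated or loaded), splits it once into
training and held-out test sets, materialises each training variant
(full, weighted, oversampled and undersampled at several case-to-control
ratios), fits each model type on each variant, and scores every model on
the same untouched test set.  Every cell draws its randomness from a
child seed derived from the global seed and the cell's identity, so
adding cells never perturbs existing ones and any cell can be re-run in
isolation.

The classification threshold for the confusion battery defaults to the
weighted case prevalence of the training variant the model was fitted on
(0.5 for balanced designs, the raw prevalence for the full data).  A
fixed 0.5 cutoff would make every low-prevalence model predict "no case"
for every row; thresholding at the fitted prevalence is an interpretive
choice, flagged here and in the methods notes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (EffectConfig, child_seed, generate_cohort,
                     read_cohort_csv, split_train_test, split_xyw)
from .ensembles import GiniForestClassifier, GradientBoostedTreesClassifier
from .evaluation import confusion_metrics
from .resampling import ResamplingPlan, apply_plan, replication_plans
from .tree import GiniTreeClassifier

logger = logging.getLogger("rebalance")

MODELS = ("cart", "cart_1se", "forest", "boost")
METRIC_ROWS = ["AUC", "Sensitivity", "Specificity", "PPV", "NPV",
               "Classification rate"]


@dataclass
class ExperimentConfig:
    """Full description of one experiment grid.

    The default mirrors the reference design: a 4677-row cohort at 3%
    prevalence split 3264/1413, eight training variants, four model
    types, CART at cp 0.01 / minsplit 20, forest of 500 trees, boosting
    with 100 trees.
    """

    n: int = 4677
    n_train: int = 3264
    cohort_csv: str | None = None  # overrides generation when set
    effects: EffectConfig = field(default_factory=EffectConfig)
    missing_rates: dict = field(default_factory=lambda: {
        "education": 9 / 4677, "marital": 2 / 4677})
    plans: list = field(default_factory=lambda: [
        ("none", None), ("weight", 1),
        ("oversample", 1), ("oversample", 2), ("oversample", 4),
        ("undersample", 1), ("undersample", 2), ("undersample", 4)])
    models: list = field(default_factory=lambda: list(MODELS))
    cp: float = 0.01
    minsplit: float = 20
    cv_folds: int = 10
    forest_trees: int = 500
    boost_trees: int = 100
    threshold: float | None = None  # None -> training-variant prevalence
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = self.effects.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "effects" in d and d["effects"] is not None:
            d["effects"] = EffectConfig.from_dict(d["effects"])
        if "plans" in d:
            d["plans"] = [tuple(p) for p in d["plans"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _fit_and_score(model: str, train: pd.DataFrame, test: pd.DataFrame,
                   config: ExperimentConfig, seed: int):
    X, y, w = split_xyw(train)
    Xt, yt, _ = split_xyw(test)
    if model == "cart":
        clf = GiniTreeClassifier(cp=config.cp, minsplit=config.minsplit)
    elif model == "cart_1se":
        clf = GiniTreeClassifier(select="1se", cv=config.cv_folds,
                                 minsplit=config.minsplit, random_state=seed)
    elif model == "forest":
        clf = GiniForestClassifier(n_estimators=config.forest_trees,
                                   random_state=seed)
    elif model == "boost":
        clf = GradientBoostedTreesClassifier(n_estimators=config.boost_trees,
                                             random_state=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(X, y, sample_weight=w)
    scores = clf.predict_proba(Xt)[:, 1]
    thr = (config.threshold if config.threshold is not None
           else float((w * y).sum() / w.sum()))
    return clf, confusion_metrics(scores, yt, thr)


@dataclass
class ExperimentResult:
    """Tidy per-cell metrics plus failures and provenance."""

    grid: pd.DataFrame  # columns: plan, ratio, model, metrics..., seed
    failures: list
    config: ExperimentConfig

    def table(self, model: str) -> pd.DataFrame:
        """Metrics-by-variant table for one model type, laid out with
        the six metric rows and one column per training variant."""
        sub = self.grid[self.grid["model"] == model]
        cols = {}
        for _, row in sub.iterrows():
            rep = row["report"]
            cols[row["label"]] = pd.Series(rep.as_row())
        return pd.DataFrame(cols).reindex(METRIC_ROWS)


def run_experiment(config: ExperimentConfig,
                   out_dir=None) -> ExperimentResult:
    """Run the full grid; optionally write CSV/JSON artifacts."""
    seed = config.seed
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
    else:
        cohort = generate_cohort(config.n, config.effects,
                                 seed=child_seed(seed, "cohort"))
        from .cohort import inject_missing
        cohort = inject_missing(cohort, config.missing_rates,
                                seed=child_seed(seed, "missing"))
    train, test = split_train_test(cohort, config.n_train,
                                   seed=child_seed(seed, "split"))

    records = []
    failures = []
    for method, ratio in config.plans:
        plan_seed = child_seed(seed, "plan", method, ratio)
        plan = ResamplingPlan(method, ratio, seed=plan_seed)
        try:
            variant = apply_plan(train, plan)
        except Exception as exc:  # noqa: BLE001 - cell isolation
            logger.exception("plan %s failed", plan.label)
            for model in config.models:
                failures.append({"label": plan.label, "model": model,
                                 "error": str(exc)})
            continue
        for model in config.models:
            cell_seed = child_seed(seed, "cell", method, ratio, model)
            try:
                _, report = _fit_and_score(model, variant, test, config,
                                           cell_seed)
            except Exception as exc:  # noqa: BLE001
                logger.exception("cell (%s, %s) failed", plan.label, model)
                failures.append({"label": plan.label, "model": model,
                                 "error": str(exc)})
                continue
            logger.info("cell (%s, %s) seed=%d auc=%.3f",
                        plan.label, model, cell_seed, report.auc)
            records.append({
                "label": plan.label, "plan": method, "ratio": ratio,
                "model": model, "seed": cell_seed, "report": report,
                **report.to_dict()})
    grid = pd.DataFrame.from_records(records)
    result = ExperimentResult(grid, failures, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = grid.drop(columns=["report"])
        flat.to_csv(out / "metrics.csv", index=False)
        for model in config.models:
            if (grid["model"] == model).any():
                result.table(model).to_csv(out / f"table_{model}.csv")
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump({"cells": flat.to_dict(orient="records"),
                       "failures": failures}, fh, indent=1)
        config.to_yaml(out / "config.yaml")
    return result


def run_replicates(config: ExperimentConfig, n_replicates: int,
                   out_dir=None) -> list[ExperimentResult]:
    """Repeat the experiment with per-replicate child seeds."""
    results = []
    for r in range(n_replicates):
        rep_cfg = ExperimentConfig.from_dict(config.to_dict())
        rep_cfg.seed = child_seed(config.seed, "replicate", r)
        sub = None if out_dir is None else Path(out_dir) / f"rep{r:03d}"
        results.append(run_experiment(rep_cfg, out_dir=sub))
    return results


def summarize_replicates(results: list[ExperimentResult]) -> dict:
    """Cell-wise median and IQR of every metric across replicates, plus
    the count of replicates in which each resampled cell beats the
    full-data cell of the same model type on AUC."""
    if not results:
        raise ValueError("need at least one result grid")
    keys = ["label", "model"]
    shapes = [tuple(map(tuple, r.grid[keys].itertuples(index=False)))
              for r in results]
    if len(set(shapes)) != 1:
        raise ValueError("result grids have different shapes")
    metrics = ["auc", "sensitivity", "specificity", "ppv", "npv",
               "classification_rate"]
    stacked = pd.concat([r.grid[keys + metrics] for r in results])
    grouped = stacked.groupby(keys, sort=False)
    median = grouped.median(numeric_only=True)
    q1 = grouped.quantile(0.25, numeric_only=True)
    q3 = grouped.quantile(0.75, numeric_only=True)
    iqr = q3 - q1

    wins = {}
    for r in results:
        g = r.grid.set_index(keys)
        for (label, model) in g.index:
            if label == "full":
                continue
            try:
                base = g.loc[("full", model), "auc"]
            except KeyError:
                continue
            wins.setdefault((label, model), 0)
            if g.loc[(label, model), "auc"] > base:
                wins[(label, model)] += 1
    return {"median": median, "iqr": iqr, "auc_wins_vs_full": wins,
            "n_replicates": len(results)}


def replication_config(seed: int = 0) -> ExperimentConfig:
    """The preset matching the reference experiment's grid."""
    return ExperimentConfig(seed=seed)


__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "run_replicates", "summarize_replicates", "replication_config",
           "replication_plans", "MODELS", "METRIC_ROWS"]
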