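# rebalance

Resampling strategies for class-imbalanced cohort data, evaluated with
classification trees.

Many clinical and epidemiological outcomes are rare: in a cohort where only
~3% of participants carry the outcome (here, undiagnosed diabetes meeting
WHO glycemic criteria in adults without a self-reported diagnosis), a
classifier trained to maximise accuracy learns to call everyone negative.
`rebalance` implements the standard remedies — random **oversampling** of
cases with replacement, random **undersampling** of controls without
replacement, and **class weighting**, each at a chosen case-to-control
ratio 1:r — and measures what they buy for CART-style decision trees,
random forests, and gradient-boosted trees on a held-out test split.

The tree engine is written from scratch. A node holding class proportions
p₁, p₂ has Gini impurity

    G = 1 − p₁² − p₂²,

and a split of a node of weight W into children (W_L, W_R) is scored by the
decrease G − (W_L/W)·G_L − (W_R/W)·G_R, searched exhaustively over numeric
thresholds and categorical level subsets, with case weights throughout.
Grown trees are pruned by weakest-link cost-complexity pruning on the
majority-vote misclassification risk, with the complexity parameter either
fixed (cp = 0.01) or chosen by stratified cross-validation with the 1-SE
rule. On top of the same engine sit a random forest (bootstrap + per-node
feature subsampling, 500 trees) and gradient boosting of the Bernoulli
deviance (depth-1 trees, shrinkage 0.1, bag fraction 0.5, 100 trees).

Because the cohort that motivated this design is not redistributable at the
row level, the package ships a synthetic-cohort generator that reproduces
its published structure: n = 4677 adults, ≈3% outcome prevalence, and a
logistic outcome model in which risk rises with age, BMI and Mexican
American race and falls with education and family poverty-income ratio,
with sparse missingness in education and marital status.

## Worked example

```python
import rebalance as rb
from rebalance.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=1, models=["cart"])   # 4677 rows, 3% prevalence
res = run_experiment(cfg)
print(res.table("cart").to_string())
```

```
                       full weight 1:1 oversample 1:1 oversample 1:2 oversample 1:4 undersample 1:1 undersample 1:2 undersample 1:4
AUC                    0.50       0.67           0.63           0.63           0.60            0.72            0.62            0.68
Sensitivity          100.0%      58.5%          53.7%          36.6%          34.1%           65.9%           36.6%           46.3%
Specificity            0.0%      75.4%          74.9%          87.8%          92.9%           68.7%           74.9%           83.4%
PPV                    2.9%       6.6%           6.0%           8.2%          12.6%            5.9%            4.2%            7.7%
NPV                     N/A      98.4%          98.2%          97.9%          97.9%           98.5%           97.5%           98.1%
Classification rate    2.9%      74.9%          74.3%          86.3%          91.2%           68.6%           73.7%           82.3%
```

One column per training variant, all scored on the same untouched 30% test
split. On the full (imbalanced) training data the cp-pruned tree collapses
to its root — every test row receives the training prevalence as its score,
the AUC is 0.50 and no metric is informative (PPV prints N/A when no
negative/positive calls exist to condition on). Undersampling the controls
to a 1:1 ratio lets the tree find real structure: AUC 0.72 on the identical
test set. The same comparison is available for `cart_1se`, `forest` and
`boost` model types, and `run_replicates`/`summarize_replicates` give
per-cell medians, IQRs and win counts across replicated cohorts.

The same stages are scriptable from a shell:

```sh
rebalance generate --n 4677 --seed 1 --out cohort.csv
rebalance resample --method under --ratio 1 --seed 1 --in train.csv --out under.csv
rebalance fit --model cart --in under.csv --model-out tree.json
rebalance predict --model-file tree.json --in test.csv --out scores.csv
rebalance run --config config.yaml --out results/
```

## Layout

- `rebalance.cohort` — synthetic cohort generator, missingness injection, train/test split, CSV I/O
- `rebalance.resampling` — oversample / undersample / class-weight plans
- `rebalance.tree` — `GiniTreeClassifier` and the impurity/pruning primitives
- `rebalance.ensembles` — `GiniForestClassifier`, `GradientBoostedTreesClassifier`
- `rebalance.evaluation` — AUC, ROC curve, confusion battery, 2×2 chi-square
- `rebalance.pipeline` — the resampling × model experiment grid
- `rebalance.cli` — the `rebalance` command

Estimators follow the scikit-learn `fit`/`predict_proba` contract and
compose with its model-selection tools; see `docs/methods.md` for the
modelling choices and their rationale.
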