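# Methods

This note documents the models and procedures implemented in `rebalance`,
the defaults and why they were chosen, and what the synthetic cohort does
and does not emulate.

## The problem setting

A binary-outcome cohort is class-imbalanced when one class dominates
(here ≈97% controls). Tree classifiers trained on such data optimise
overall purity, which a "predict control for everyone" tree already nearly
achieves, so they underfit the minority class. The package studies three
remedies applied to the *training split only*:

- **oversampling** — draw cases uniformly with replacement until the
  case count reaches ⌈n_control / r⌉ for a target ratio 1:r (the ceiling
  is forced by the combined design sizes 6330/4748/3957 reached from 3165
  controls at r = 1, 2, 4);
- **undersampling** — draw exactly r·n_case controls uniformly without
  replacement;
- **class weighting** — keep all rows, give controls weight 1 and each
  case weight n_control/(r·n_case), so total class weights stand at 1:r.

Resampling never touches the held-out test split, and the full-data cell
of the experiment grid uses the training split untouched.

## The tree engine

**Splitting.** Node purity is Gini impurity G = 1 − p₁² − p₂², computed on
total case weights. The engine exploits the identity that, for a 0/1
response, the size-weighted child impurity sum is twice the weighted sum
of squared errors; a single weighted least-squares split search therefore
serves both the classification trees (exactly equivalent to Gini) and the
regression trees used inside boosting. Numeric candidates are midpoints
of consecutive distinct observed values. Categorical levels are ordered
by weighted case proportion (mean response, for boosting's gradients) and
only contiguous subsets in that order are scanned, which is optimal for
two-class Gini and for least squares; an ordered education factor is
handled the same way, since for a binary outcome the optimal ordered and
unordered subsets coincide whenever the class proportions are monotone in
the level order.

**Missing values and unseen levels.** A row missing the split variable
follows the majority-weight side of that split, recorded on the rule.
This is a deliberate simplification of surrogate splits; in the emulated
cohort missingness touches ≈0.2% of education/marital cells, so the two
conventions can differ only on that sliver of rows. A categorical level
never seen in training routes the same way, with a warning.

**Weights.** `minsplit` (smallest splittable node, default 20) and
`minbucket` (smallest child, default round(minsplit/3) = 7) are measured
in total weight, so a case carrying integer weight k behaves identically
to k replicated rows — a property the tests assert node-for-node. The
phrase "minimum partition size" is ambiguous between the two parameters;
both are exposed, with the 20 applied to `minsplit`.

**Stopping and pruning.** Growing accepts any split with a positive
impurity decrease, then weakest-link cost-complexity pruning is applied
on the *risk* scale: a leaf's risk is min(w_case, w_control) (weighted
misclassification under majority-vote labels) and the complexity
parameter cp is expressed relative to the root risk. Pruning at cp is
equivalent to rejecting during growth any subtree whose risk improvement
per leaf falls below cp × root risk, and matches the convention of the
classical recursive-partitioning implementations: on an imbalanced cohort
where no leaf becomes case-majority, every split has zero risk
improvement and the cp-pruned tree collapses to its root (verified
side-by-side against R's rpart on a synthetic cohort). This is precisely
the underfitting phenomenon the resampling designs repair: on a 1:1
resampled table the same splits carry large risk decreases and survive.

**Ties.** The split search maximises the impurity decrease with
deterministic tie-breaking: lexicographically smallest predictor name,
then smallest threshold (numeric) or smallest left subset (categorical).
Thresholds are midpoints, so they never coincide with observed values.

**Cross-validated cp (1-SE rule).** The pruning path yields thresholds
α₀ = 0 < α₁ < …; each path entry is evaluated at the geometric mean
√(α_k α_{k+1}) of its interval. Ten stratified folds (cases and controls
dealt round-robin after shuffling; re-dealt up to 10 times if a training
part lacks a class) each grow their own tree, prune it at the candidate
times *their own* root risk, and score the held-out fold by weighted
misclassification. Risks are normalised by the full-data root risk; the
SE is the between-fold standard error. The selected cp is the largest
threshold whose cross-validated risk is within one SE of the minimum —
on data the tree cannot beat the majority rule, that is the root-only
tree. The fold count is a package choice (10 is the common default; the
design being emulated did not state one).

## Ensembles

**Random forest** (default 500 trees): each tree is grown unpruned
(minbucket 1) on a bootstrap resample of n rows, with a fresh uniform
draw of mtry = ⌊√p⌋ features at every node. A weighted training design is
honoured by drawing the bootstrap with selection probability proportional
to weight, after which rows count 1 each. The forest score is the mean
leaf case proportion; out-of-bag index sets are retained.

**Gradient boosting** (default 100 trees): gradient descent on the
Bernoulli deviance from F₀ = logit(weighted prevalence). Each step fits a
depth-limited (default depth 1) least-squares tree to the residual y − p
on a 50% bag, replaces each leaf value by the one-step Newton update
Σw(y−p)/Σwp(1−p) over the in-bag leaf rows, and adds 0.1 × the increment.
Case weights enter the gradient fit and the Newton updates. Defaults
(depth 1, shrinkage 0.1, bag 0.5, minimum terminal weight 10) follow the
conventional defaults of the classical boosted-tree packages, since the
emulated design specified only the ensemble sizes (500 and 100).

## Evaluation

AUC is the midrank Mann–Whitney statistic: the probability a random case
outscores a random control, ties counted ½; the ROC polyline integrates
to exactly this value. The confusion battery (sensitivity, specificity,
PPV, NPV, classification rate) is computed at "positive iff score ≥
threshold"; a predictive value with an empty denominator is reported as
N/A, never as 0. The 2×2 incidence comparison uses Pearson's chi-square
*without* continuity correction — the convention that reproduces the
printed χ² = 0.14 (p = 0.71) from counts 99/3165 vs 40/1373; with Yates
correction the statistic would be ≈0.06.

**Operating threshold.** The design being emulated does not state how its
confusion entries were produced, and a fixed 0.5 cutoff is degenerate for
low-prevalence models (no leaf reaches case-majority). The pipeline
therefore defaults the threshold to the weighted case prevalence of the
training variant the model was fitted on — 0.5 for balanced designs, the
raw prevalence for the full data — with an explicit override. This is an
interpretive choice and is flagged as such.

## The synthetic cohort

The generator emulates a 4677-adult health-survey cohort. Categorical
predictors (gender, 5-level race, 5-level ordered education, 6-level
marital status) are drawn from its published marginal frequencies; age is
uniform within its published decade bands (70+ spread over 70–84); BMI
and poverty-income ratio are normal with the published means and SDs,
clipped to plausible ranges (BMI 14–70, PIR top-coded at 5). The outcome
is Bernoulli with logit risk linear in centred age (+0.045/yr), BMI
(+0.115/unit), PIR (−0.15/unit), education level (−0.2/level) and race
contrasts (Mexican American +0.85, Non-Hispanic Black +0.35 vs
Non-Hispanic White), signed to match the published case/control
contrasts and sized to give odds ratios in the range such survey analyses
report; the intercept is calibrated by root-finding so expected
prevalence hits the 3% target on the drawn covariates. Missingness is
injected only into education and marital status (default rates 9/4677
and 2/4677).

Limitations: predictors are mutually independent (only marginals are
published; a joint model would need the row-level data), missingness is
completely at random, and the outcome model is exactly logistic — so
tests passing on this cohort demonstrate correctness of the machinery
and the direction of resampling effects, not the numeric performance any
real cohort would give. The train/test split is unstratified simple
random sampling with an explicit integer training size (floor(0.7n) by
default, 3264 in the replication preset, matching the emulated design's
printed 3264/1413 rather than the rounded 3274).

## Seeds and determinism

A single global seed expands into named child seeds per stage
(`child_seed(seed, *tags)`, SHA-256 based, < 2³¹), and each grid cell
derives its seed from (seed, plan, ratio, model) — so adding cells never
perturbs existing ones, and any cell can be reproduced in isolation from
its logged seed. All estimators are deterministic given their
`random_state`.

## Problem sizes in the test suite

The oracle-equivalence tests run brute-force enumeration on tables of
30–200 rows (50 random tables for the split search, 50 score vectors for
AUC, exhaustive subtree search on 50-row trees); the directional
replication uses 20 cohorts of 4677 rows with CART only. These sizes make
the full suite complete in well under a minute of tree growing while
keeping every check at the scale where its oracle is exact.
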