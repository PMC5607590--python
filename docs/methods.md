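# Methods

## Model

Both tree methods fit the same piecewise-constant regression model: a
binary tree of axis-aligned split rules whose terminal nodes partition the
covariate space; the prediction in a terminal node is the arithmetic mean
of the training outcomes it contains. Routing sends `x ≤ threshold` left;
binary 0/1 covariates split at 0.5 so that value 0 goes left. Node IDs are
assigned by depth-first preorder with the root labelled 1, matching the
numbering convention of standard conditional-inference-tree displays (the
terminal nodes of a depth-3 tree with a deeper left branch are 3, 5, 6, 7).
Inputs must be complete: there are no surrogate splits, and a missing value
on a routing path raises an error. Only continuous outcomes are supported.

## CART

Greedy SSE search: at a node the split maximising
`SSE(parent) − [SSE(left) + SSE(right)]` is sought over every covariate and
every midpoint between consecutive distinct sorted values (a binary
covariate contributes the single candidate 0.5). Midpoint candidates —
rather than an equally spaced grid — make the search exact and let a
brute-force enumeration act as an independent oracle in the tests. Ties are
broken by covariate order, then by the smallest threshold, so fits are
deterministic. A node is split only when it holds ≥ `minsplit` (default 20)
observations, both children would hold ≥ `minbucket` (default 7), and the
reduction is at least `cp × SSE(root)` (default `cp = 0.01`, i.e. "improve
fit by ≥ 1%"). The cp scale is always relative to the *root* of the tree
being grown, including inside cross-validation folds.

**Pruning.** Weakest-link cost-complexity pruning collapses, at each step,
every internal node with minimal per-split error increase
`g(t) = [SSE(t) − Σ_leaves SSE]/(leaves(t) − 1)` (normalised by root SSE),
yielding a nested subtree sequence with non-decreasing critical cp values.
K-fold cross-validation (default K = 10; seeded, balanced random fold
assignment) estimates each subtree's prediction error: every fold tree is
grown with the same parameters and pruned at the geometric midpoint of the
consecutive critical cp values — except the root-only entry, which is
evaluated at cp = ∞ so its CV error is the clean mean-prediction error in
every fold. This choice matters: evaluating the root row at a finite
penalty lets fold trees keep splits, inflating the root's apparent error
and with it the null Type-I-error rate of the min rule by a factor of ~5.
The standard error of a subtree's CV error is the standard deviation of
the per-observation squared errors divided by √n. Rule `min` picks the
subtree minimising mean CV error; `one_se` the smallest subtree within one
SE of that minimum; ties favour the smaller subtree.

## Conditional inference trees

At each node every candidate covariate is tested for marginal association
with the outcome via the linear statistic `T = Σ x_i y_i`. Under the
permutation null its exact moments are `E[T] = n x̄ ȳ` and
`Var[T] = S_xx S_yy/(n − 1)`, so the standardized statistic is
`z = r √(n − 1)`; two-sided p-values use the standard normal reference.
This permutation-asymptotic choice is implementation-defined (any
equivalent standardized regression-coefficient test would do) and is
verified in the tests against exact enumeration of all 8! permutations on
a small fixture, and for calibration against uniformity of the null
p-value distribution. Constant covariates get p = 1 by convention.

Multiplicity adjustment is Bonferroni over the covariates tested at the
node (per-node, not tree-wide): `p_adj = min(1, m·p_raw)`. The node splits
iff `min p_adj ≤ α` (default 0.05); the covariate attaining the minimum is
selected (ties → column order). The split point then maximises the
absolute standardized two-sample statistic of `1(x ≤ c)` against the
outcome over midpoint candidates respecting `minbucket`; an SSE-based
split-point rule is available behind `split_criterion="sse"` but is not
the default, preserving the inference-based construction. Because variable
and split-point selection do not depend on α, the tree at a smaller α is
always a pruned subtree of the tree at a larger α.

## Confounder adjustment

`fit_adjustment` fits `Y = β₀ + β₁C₁ + … + β_kC_k + ε` by OLS
(statsmodels); `adjusted_residuals` returns `Y* = Y − Xβ̂`, which is used
as the tree outcome with the confounders removed from the candidate set.
Adjustment and tree fitting deliberately use the same sample. Rank-deficient
designs are rejected with the collinear columns named. `standardize`
z-scores columns (denominator n − 1) and keeps means/SDs for
back-transformation to original units.

## Subgroup visualization

One panel per terminal node: a histogram of the subgroup's outcome values
(equal-width bins over the subgroup range, default 10 — the bin count is a
display choice), each bin annotated with its mean outcome; a vertical line
at the subgroup mean, with mean and size in the title; and one horizontal
bar per covariate in the subgroup rule, whose endpoints are the rule
interval mapped through the *full-sample* empirical CDF
(`percentile = 100 × fraction ≤ value`; ±∞ → 0/100). The full sample — not
the parent node — is the reference, matching the "population percentile"
reading. The empirical-CDF definition (no interpolation) makes the bars
exactly invertible up to sample discreteness, which the tests exploit.
Grids are ⌈√L⌉ columns for L leaves; PNG/SVG/PDF are supported, and SVG
output embeds the panel specifications as JSON metadata so rendered
numbers can be recovered programmatically. Bar colors follow covariate
order and are purely presentational.

## Simulation study

Defaults follow the study conditions: n = 250 training and an equally
sized, independently generated test set; six covariates, i.i.d. N(0,1)
(or Bernoulli(0.5) when binary); `minsplit = 20`, `minbucket = 7`,
`cp = 0.01`, `α = 0.05`. DGPs:

* **tree** — a fixed 7-leaf tree on X1–X4 (X5, X6 noise) with leaf means
  (−1.88, −0.30, −0.31, 0.25, −0.09, 2.23, 1.35) and unit variance. Only
  the leaf means and split variables are prescribed; the topology and
  thresholds (1.69, −0.28, −1.26, 0, echoing the introductory example's
  printed cutpoints) are this package's choice and are configurable, so
  tree-scenario aggregates are qualitative rather than exact reproductions.
* **regression** — `η = 1.5X₁ + 1.25X₂ + X₃ + 0.85X₄ + 0.75X₅ + 0X₆`.
* **hybrid** — `η = 0.5X₁ + 0.45X₂ + 0.3X₃ + 1.5·1(X₁≤0, X₂>0, X₃≤0)
  + 0.25·1(X₁≤0, X₃>0) + 0.14·1(X₁>0, X₂>0)`, with X4–X6 as noise so six
  covariates are always offered. The OLS comparator includes main effects
  of all six covariates (the three extra null effects change its expected
  MSE by ~p/n only).
* **null** — y ~ N(0,1) independent of all covariates; a Type-I error is
  any split at all.

Each replicate draws an independent child stream from one master seed
(`SeedSequence.spawn`), so results are reproducible and replicates could be
parallelised without changing them; CV fold seeds derive from the same
stream. Aggregates report MSE mean/SD, node-count mean with nearest-rank
20th/80th percentiles, and the Type-I-error rate.

The generator emulates the study conditions exactly but not features of
real cohort data — correlated covariates, skewed or heteroscedastic
outcomes, measurement error, missingness — so passing tests demonstrate
method behaviour under clean Gaussian conditions, not field performance.

## Problem sizes and tolerances

The packaged checks run desk-scale replicate counts (500–2,000 instead of
the study's 10,000; 200 per size for the sample-size sweep over
n = 250…5,000), with acceptance bands of roughly three Monte-Carlo
standard errors around the published means. Two published null-DGP figures
are documented but not tested against: the unpruned-CART MSE of 0.65 and
the linear-regression MSE of 0.97, both below the test-error noise floor
of 1 and hence not reproducible under an independent-test-set convention.

## Known limitations

Continuous outcomes only (no classification or survival trees); no
surrogate splits or missing-data handling; no ensembles; Bonferroni is the
only multiplicity adjustment; p-values are asymptotic, so they are
slightly conservative at very small node sizes; trees describe
associations, not causal effects — adjustment removes confounding only for
measured confounders entering linearly.
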