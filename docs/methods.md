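# Methods

## The hierarchy and its comparison matrices

A factor hierarchy has one root ("risk score"), criterion /
sub-criterion layers, and leaf factors bound to dataset variables. The
default tree has three main criteria — demography (region, age, gender,
education, disability grade, social support, economic status), treatment
(adverse reaction, compliance, treatment, drug combination) and disease
course (hospitalizations, risk events, annual policy, duration) — so every
node has between 2 and 9 children, the range over which the random-index
table is defined.

Pairwise comparison matrices are positive and reciprocal (`a_ii = 1`,
`a_ji = 1/a_ij`) with entries on Saaty's scale {1/9 … 1/2, 1 … 9}. For any
such matrix the principal eigenvalue satisfies λ_max ≥ n, with equality
exactly at consistency (`a_ij·a_jk = a_ik`); the consistency index is
CI = (λ_max − n)/(n − 1) and the consistency ratio CR = CI/RI with the
standard random-index table RI(1..9) = 0, 0, 0.58, 0.90, 1.12, 1.24, 1.32,
1.41, 1.45. A matrix is accepted when CR < 0.10; orders ≤ 2 are always
consistent (RI = 0, CR defined as 0).

**Eigen-solver.** Priorities come from power iteration with L1-normalized
iterates (tol 1e-10, max 10,000 iterations); for a consistent matrix the
first multiply is already exact because the matrix has rank one. λ_max is
re-estimated from any weight vector W as (1/n)·Σ_i (AW)_i / W_i, which is
exact in the consistent case and serves as a cross-check of the power
iteration (the two agree to ≤1e-6 on consistent matrices, ≤1e-3 relative on
acceptable ones).

**Automatic construction.** Given a nonnegative weight vector (learned or
expert-supplied), the matrix `a_ij = w_i/w_j` is perfectly consistent;
weights below 1e-6 are floored to keep ratios finite. Quantization maps
each ratio to the log-space-nearest admissible Saaty value, treating x and
1/x symmetrically; ties break toward 1 (the smaller absolute grade) for
conservatism. Quantization can push CR above 0.10 for low orders, where
the log-grid gaps are widest relative to RI.

**Repair.** The repair loop recomputes the principal eigenvector, replaces
the entry with the largest |log(a_ij·w_j/w_i)| by the (grid-snapped) ratio
implied by the eigenvector, and repeats, at most 50 rounds; matrices that
arrived on the Saaty grid never leave it. If no single entry can move, the
whole matrix is rebuilt from the current eigenvector. Already-acceptable
input is returned unchanged; failure to reach CR < 0.10 raises an error
naming the worst entry.

**Synthesis.** Leaf global weights are products of local weights along the
root path and sum to one by construction. The combination consistency test
aggregates Σ(node global weight · CI) over Σ(node global weight · RI)
across internal nodes, with the same < 0.10 acceptance; nodes of order ≤ 2
contribute nothing to either sum.

## Cox weighting

`fit_cox` maximizes the Breslow partial likelihood by Newton iterations
with step-halving, so the log-likelihood never decreases across accepted
steps; covariates are centered internally, constants dropped with a
warning, and convergence is a gradient sup-norm below 1e-7. Standard
errors come from the observed information; hazard ratios carry Wald 95%
CIs. Breslow tie handling is adequate here because event times are nearly
continuous; the implementation matches lifelines to ~1e-3 on shared fits.
The durations passed to the fit must be the **observed** times
(min(event time, end of follow-up)) — feeding the scheduled follow-up
window instead attenuates every coefficient, because subjects then appear
at risk after their event.

Hierarchy weight seeds are normalized |β| magnitudes, so protective and
harmful effects contribute symmetrically; an option restricts seeding to
|z| ≥ 1.96 coefficients (off by default). Criterion-level weights are the
summed leaf magnitudes beneath each criterion.

## Age–period–cohort adjustment

Event counts on an age-group × period grid (exposures in person-years) are
modelled by a Poisson working model with log link. Age and period are
sum-to-zero fixed effects; the cohort diagonal (cohort = period − age) is a
random effect realized as an L2 penalty on the cohort contrasts, which
resolves the classical APC identification problem by attributing the shared
linear trend to the fixed axes. The penalty weight is selected on a fixed
log-spaced grid (1e-1 … 1e5) by a Laplace approximation to the marginal
likelihood of the cohort block; the reported cohort variance is its
reciprocal. `period_adjust` subtracts the fitted period effect on the
linear-predictor scale, leaving within-period ordering untouched — after
adjustment a pure-period simulation is period-flat (residual slope below
0.02 at the 20×10/1,000-per-cell design used in the tests).

## Supervised discretization

Continuous variables are cut into risk levels by bottom-up merging of 20
equal-frequency seed bins: while the Wilson confidence intervals of
adjacent bins' event rates overlap, the pair with the smallest pooled
two-proportion z statistic is pooled. Two numerical choices matter and are
deliberate:

* the pairwise intervals use a familywise (Bonferroni-adjusted) confidence
  level across the seed boundaries — with per-pair intervals, greedy
  pooling gradually isolates single noisy seed bins, and a ~2.5σ
  fluctuation then survives as a spurious level;
* after merging, each surviving cut is refined to the position maximizing
  the contrast between its flanking bins and the merge re-run (twice at
  most) — an equal-frequency boundary that straddles a true change point
  otherwise leaves a genuinely intermediate-rate sliver bin.

With both, a simulated two-piece rate (0.05/0.30, n = 5,000) is recovered
as exactly two bins with the cut within ±2 units of the change point in
100/100 seeded replicates. Bins are half-open `[lo, hi)` with the last bin
closed; a value equal to a cut belongs to the upper bin and out-of-range
values clip to the end bins. Every final bin holds at least `min_frac`
(default 5%) of the rows; each level carries its count, event rate, Wilson
CI at the nominal confidence (default 0.95), and a nomogram-style score:
the smoothed log-odds of the level relative to the marginal rate.

## Feature ranking

Six indicators are computed per candidate variable against the binary
outcome: information gain and gain ratio (entropies in bits, so a perfect
predictor of a balanced outcome scores exactly 1), Gini gain, Pearson χ²
(zero margins dropped with a warning), ReliefF (k = 10 neighbours, all
rows sampled, min-max scaled features, seeded) and FCBF symmetric
uncertainty SU = 2·IG/(H(x)+H(y)) with predominance pruning (threshold 0,
i.e. keep all and prune redundancy only). Per-indicator ranks (1 = best,
midpoint ties) are averaged into the ensemble rank; undefined or
not-selected cells are excluded from the average rather than imputed.
Selection takes the top-k (default 23) and applies expert keep/drop lists.

## Risk scores and evaluation

Leaf level scores are min-max-normalized smoothed log-odds (0 = lowest-risk
level, 1 = highest); a single-level leaf scores 0.5 with a warning. The
patient score Σ w_leaf·s_leaf(level) is monotone in every leaf. Missing
levels impute the training-majority level with a warning; unseen *numeric*
levels clip to the nearest training level (the analogue of end-bin
clipping), unknown categorical levels raise an error naming the leaf.

AUC is the Mann–Whitney rank statistic with midrank ties (identical to the
O(n²) concordance count). Precision/recall/F1 use class-weighted
averaging, under which accuracy equals weighted recall — the identity the
harness asserts. The classification threshold maximizes weighted F1 on the
training split over the observed score values (so the chosen
classification is invariant under monotone score transforms), tie-breaking
to the lower threshold. Propensity matching is greedy 1:1
nearest-neighbour without replacement within a caliper of 0.2·SD of the
scores (the common convention). Baselines are scikit-learn classifiers
with fixed hyper-parameters (random forest 1,000 trees / 5 split
attributes; MLP 100 hidden ReLU units, Adam, lr 0.001, 200 iterations;
ridge logistic C = 1; SGD logistic with elastic net, ε 0.1, 1,000
iterations; kNN k = 9 Euclidean uniform; RBF SVM C = 1, γ = 0.1, 100
iterations; Gaussian naive Bayes), all evaluated through the same harness.

## The synthetic cohort generator

One row is one patient-course. Covariates are drawn from declared
marginals (compliance balanced at 0.5; female fraction 0.45; five regions
with log-hazard offsets −0.5 … +0.5; periods 2010–2019 with a +0.3
log-hazard policy step from 2015; counts Poisson; ordinal ratings
uniform). Event times are exponential proportional hazards with linear
predictor Σ β_j x_j + region offset + policy step; the published Cox
log-hazards serve as coefficient defaults (the "duration" effect 0.05
attaches to the ordinal course-of-disease rating derived from an
independent years-since-onset variable — the follow-up window itself
carries no coefficient, since a covariate deterministically equal to the
censoring horizon is degenerate in a Cox fit). The baseline hazard is
calibrated by bisection so that in expectation 15% of records experience
the event within their follow-up (a configurable default, not a claim
about any real prevalence); censoring is the end of follow-up. The
generator emits the exact ground-truth record alongside the table, and the
same seed reproduces the CSV byte-for-byte.

What it does **not** emulate: longitudinal repeated measures per patient,
covariate dependence structures (all covariates are independent given
region/period), real-world marginals, informative censoring, or
non-proportional hazards. Passing tests therefore demonstrate the
correctness of the machinery under the declared model, not performance on
registry data.

## Pipeline conventions and problem sizes

The pipeline splits the cohort 2:1 (stratified, seeded), learns bins,
ranking, Cox weights and the scorecard on the training two-thirds, and
reports metrics on train, test and the full cohort. The
composite-versus-single-feature comparison is made on the full cohort with
feature directions learned on train: on a ~670-row test third the maximum
over ~15 single-feature AUCs is inflated by ~0.04 and beats even the
true-model linear predictor on about half the splits, so the full-cohort
basis is the one that measures model value rather than split luck.

Default problem sizes: the pipeline demo and end-to-end tests use 2,000
rows; coefficient-recovery experiments use 20,000 rows (sampling SE of a
balanced binary coefficient ≈ 0.037 at a 15% event rate);
discretization-recovery replicates use 5,000 rows; the APC recovery grid is
20 age groups × 10 periods at 1,000 exposure units per cell. Every run
writes a manifest with the config hash, seed, package version and
per-stage status; no stage mutates its input files, and a rerun with the
same config and seed reproduces the metric report exactly.

## Known limitations

* The repair loop guarantees CR < 0.10 when it returns, but the result is
  a local fix, not the nearest consistent matrix in any metric.
* The manual-override hook for blending expert edits with learned weights
  is intentionally thin (hierarchy files can carry explicit matrices or
  weights); no semantics beyond replacement are implemented.
* The APC marginal-likelihood grid search is a Laplace approximation, not
  a full mixed-model fit; cohort variance estimates are indicative only.
* Group-decision AHP, fuzzy AHP, ANP networks, time-varying covariates,
  competing risks and Efron ties are out of scope.
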