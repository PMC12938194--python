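# Methods

`ruleddm` analyses a two-choice decision task crossing an external
difficulty factor — the number of nested conditional rules a trial
requires (rule hierarchy, 3 levels) — with an intrinsic learning factor
(5 successive practice blocks).  Because the behavioural data the design
emulates cannot be shared, the package carries its own generator: every
stage is exercised end to end on synthetic cohorts whose ground truth is
known, so recovery, convergence and anti-leakage guarantees are testable
facts rather than assumptions.

## The decision model

Each trial is modelled as a Wiener diffusion with drift `v` (evidence/s),
diffusion coefficient fixed at 1, absorbing boundaries at 0 and `a`
(evidence units), start point `Z0 = z·a` with start proportion
`z ∈ (0,1)`, and non-decision time `t0` (s).  The upper boundary codes a
correct response (accuracy coding); observed RT is `t0` plus the
first-passage time.  There are no inter-trial variability parameters.

The first-passage density is evaluated with the classic dual series —
the small-time image expansion and the large-time sine series — with
truncation tolerance `eps = 1e-7`, switching to whichever representation
needs fewer terms.  Tests verify continuity at the switch point
(relative jump < 1e-6), agreement of the integrated density with the
closed-form absorption probability `(1−e^{−2vaz})/(1−e^{−2va})`, and
agreement with a fine-step simulation histogram.

Per-trial log densities are floored at −700.  This keeps Metropolis
proposals that violate the `t0 < min RT` constraint rejectable rather
than fatal, and is far below any log density that arises in practice.

### Units

The published group-level parameter table prints non-decision times
around 730–960 and boundaries around 3–6.4 without units.  The package
adopts seconds as its internal time unit and reads the non-decision
entries as milliseconds (dividing by 1000 on ingestion).  All other
quantities are taken at face value.  Only self-consistency matters for
the recovery studies: data are generated and fitted under the same
convention.

## Synthetic cohorts

`design.generate_design` reproduces the task structure: per participant,
5 blocks × (3 hierarchies × `trials_per_cell`) trials, hierarchy order
shuffled within block, a `rule_switch` flag marking trials whose
hierarchy differs from the preceding trial.  The default
`trials_per_cell = 6` gives 90 trials in blocks of 18.

Generating parameters default to the published posterior means: the
hierarchy-level profile (e.g. drift 0.92/0.60/0.38) for hierarchy-only
truth, the block-level profile for block-only truth, and their additive
combination (block deviations mean-centred around the hierarchy profile)
for two-factor truth.  `additive_population(v_interaction=g)` plants a
hierarchy×block interaction on the drift rate: the hierarchy-1 minus
hierarchy-3 drift gap grows by `g` per block.  Between-subject spread
defaults to sd 0.10 for `v` and `a`, 0.05 s for `t0` and 0.03 for `z` —
moderate individual differences that keep every subject well inside the
admissible region; subjects are drawn from the group normal truncated by
rejection (`a > 0.1`, `z ∈ (0,1)`, `t0 > 0`).

The forward simulator is Euler–Maruyama at `dt = 1 ms` with a
Brownian-bridge crossing check between grid points.  Without the bridge
correction the crossing rate carries an `O(√dt)` bias that is visible
against the closed-form absorption probability at n = 20 000; with it
the simulator passes 3-standard-error checks across random parameter
sets.  Trials that fail to absorb within 60 s are resampled.  The cap is
set far above the slowest default cell (the hierarchy-3 cell has mean
first-passage time ≈ 7.5 s) because a tight cap would silently truncate
the RT distribution the likelihood assumes; at 60 s the resampled mass
is negligible (< 1e-6).

A separate screening fixture emulates the cohort structure: 40 collected
participants, exactly 5 failing the learning-phase accuracy criterion
(< 0.80) and 1 (disjoint) failing the hierarchical-response protocol —
6 exclusions, 15%, N = 34 retained.

What the generator deliberately does not emulate: fixation jitter, cue
screens and the multi-keypress response chain (one RT per trial), the
learning-phase task itself (only its outcome flag), fatigue and
sequential dependencies beyond the cell structure.  Passing recovery
tests therefore show that the estimation machinery is correct under the
model's own assumptions, not that the model describes any particular
real dataset.

## Behavioural statistics

Participant exclusions are applied before trial trimming.  The RT
trimming rule — drop trials below 0.2 s or above the participant × cell
mean + 3 sd, in one pass — is a conventional choice (the emulated
protocol does not state one); both logs account for every removed
record.  The 3 × 5 repeated-measures ANOVA operates on participant ×
cell aggregates (mean accuracy; mean RT of correct trials).  Sums of
squares are computed directly from the balanced decomposition;
Greenhouse–Geisser epsilon comes from the covariance of orthonormally
contrast-transformed subject scores and shrinks numerator and
denominator degrees of freedom by the same factor; effect size is
partial eta squared `SS_eff/(SS_eff+SS_err)`.  The implementation is
cross-checked in the tests against a brute-force sums-of-squares oracle
and against `pingouin`.  Pairwise comparisons are paired t-tests with
Bonferroni adjustment (again a documented convention).

## Hierarchical Bayesian estimation

Four models share one machinery, differing only in the factor map every
DDM parameter follows: hierarchy-only (3 levels), block-only (5),
additive (hierarchy baselines + zero-sum block offsets, effect-coded) and
cell-wise (15).  Maps are expressed as design matrices over the 15 cells;
a subject's cell value is `X β`.  Free group-level location counts are
4×3 = 12, 4×5 = 20, 4×7 = 28 and 4×15 = 60.  (An additive model cannot
have the same free-parameter count as the full interaction model; 28 is
what the additive structure implies.)

Subject coefficients follow `N(μ, σ)` per coefficient, truncated to the
admissible region by rejection; the truncation normalising constant
(a function of μ, σ) is ignored, which is accurate while the posterior
keeps the group mass interior to the bounds — true at the default
generating values.  Hyperpriors are uniform: `v ∈ [−5, 5]`,
`a ∈ [0.1, 10]`, `t0 ∈ [0.01, 3] s`, `z ∈ [0.01, 0.99]`, offsets on the
symmetric half-ranges, and each group sd uniform on (0, half the mean
range].

Sampling is component-wise Gaussian random walk on unconstrained scales
(identity for `v` and offsets, log for `a` and the sds, logit for `z`,
range-logit for `t0`), 3 chains by default.  Every 200 iterations during
burn-in each component's step is multiplied by `exp(±0.1)` according to
whether its window acceptance is above or below the 0.30 target; the
kernel is frozen after burn-in so the retained chain is a fixed-kernel
Markov chain.  Initial subject steps scale with `√(5/c)` where `c` is
the number of design cells a coefficient covers — coefficients that see
fewer trials have flatter conditionals and need proportionally larger
steps for the multiplicative adaptation to reach the target band within
the burn-in.

Two structured moves supplement the componentwise sweep, both standard
remedies for hierarchical random-walk samplers:

* a **shift** move translates a group mean together with all its subject
  coefficients (subject deviations, and hence the hierarchical prior,
  are unchanged; only the data likelihood decides), freeing the group
  mean from its narrow conditional given the subjects;
* a **scale** move multiplies a group sd and all subject deviations by
  `e^δ` (log ratio reduces to Δloglik + δ after the prior and Jacobian
  terms), breaking the funnel coupling that otherwise stalls the sds.

Without these moves, group-level R-hat on the desk-scale recovery fit
stalls around 1.2–1.7; with them it reaches < 1.05 within 1500
iterations.  Both moves adapt their steps like any other component and
are likewise frozen after burn-in.

Convergence is summarised by the classic Gelman–Rubin ratio per
group-level parameter, with 1.05 as the operative warning threshold and
1.01 reported as the stricter reference.  Credible intervals are highest
density intervals (shortest window over `⌈0.95 n⌉` sorted draws); two
conditions differ "significantly" when their 95% HDIs are disjoint
(shared endpoints count as overlap).  The posterior predictive check
re-simulates each participant × cell at posterior means (5× the observed
trial count) and reports per-cell accuracy and RT quantile
(.1/.3/.5/.7/.9) discrepancies.

The scalar "interaction strength" summary is implemented as a documented
contrast — the mean over adjacent block pairs of the change in the
hierarchy-3 minus hierarchy-1 gap of cell means, per posterior draw —
because the quantity is not otherwise pinned down; it is configurable
per parameter and is exactly zero under factor maps that cannot express
an interaction.

## Model comparison

`AIC = 2k − 2 logL̂` and `BIC = k ln n − 2 logL̂` use the total
log-likelihood at subject posterior means, with `k` the free group-level
location count above.  One caveat is structural and documented rather
than hidden: in a hierarchical model this `k` does not price
subject-level flexibility, so AIC flatters the cell-wise model — with 60
coefficients per subject it absorbs noise worth far more than its
group-level penalty, and no plug-in variant repairs this (evaluating at
group-level means applied to all subjects is ill-defined whenever a
fast subject has trials below the group `t0`; the posterior-mean
log-likelihood shifts but does not close the gap).  The predictive
comparison is therefore the complexity-honest companion: ELPD_loo is
computed by Pareto-smoothed importance sampling from the pointwise
log-likelihood draws (via `arviz`), with per-trial k-hat > 0.7 flagged;
the standard error of a pairwise ΔELPD always comes from the pointwise
elpd differences, never from the two standard errors in quadrature, and
`ΔELPD > 2 se` is the significance rule.  Selection reports the lowest
AIC among converged fits alongside all pairwise ΔELPD flags; the
validation suites accordingly check that a planted interaction is
recovered by selection and that under a hierarchy-only truth the
cell-wise model's predictive edge over the additive model is
non-significant.

## Random forest

The 11-feature trial table mirrors the study's feature system: design
terms (`Block_ID`, `Rule_Hierarchy`, their product), model terms (cell
posterior means of `v`, `a`, `t0`, `Z0` and a per-cell mean R-hat
convergence index — `z` is excluded because `z = Z0/a` duplicates
information), and history terms (cumulative moving averages of past
accuracy and past log RT, plus the rule-switch flag).  The CMA features
at trial t average trials 1..t−1 of the same participant only; trial 1
takes a neutral initialiser (0.5 for accuracy; for log RT a supplied
constant — under cross-validation the training-fold median, so the
guarantee survives; if none is supplied the global median is used and
the provenance is flagged).  A perturbation property test freezes this:
modifying any trial at index ≥ t leaves both CMA values at trial t
unchanged.

The forests are CART ensembles written in-package: bootstrap resamples
with stored OOB sets, depth ≤ 10, leaf ≥ 5.  Classification (trial
accuracy) splits on Gini impurity with all features available per node
(pure bagging, reading the protocol literally); regression (log RT of
correct trials) splits on variance reduction with ⌈11/3⌉ = 4 features
per node.  For 0/1 targets Gini and variance splitting coincide, so one
scorer serves both.  `n_trees` defaults to 300 (unstated in the emulated
protocol; configurable).  Evaluation is OOB aggregation and grouped
5-fold cross-validation with participant-level splits (fold sizes differ
by at most one participant; the Methods-style grouped splitting is used
throughout).  F1 takes the correct class as positive.  Permutation
importance permutes one feature across the OOB sample set, re-aggregates
OOB predictions, and records the accuracy drop (classification) or RMSE
increase (regression), averaged over 50 repeats; mean drops are floored
at zero and normalised to sum to one.  A Top-8 refit (selected by
classification importance, columns kept in canonical order so
`k = n_features` reproduces the full model exactly) is reported next to
the full model.

## Problem sizes and numerical choices

The validation studies run at desk scale: parameter recovery fits 10
subjects × 90 trials with 3 chains × 1500 iterations (750 burn-in);
the convergence study fits the cell-wise model with 3 chains × 3000
(1500 burn-in); the selection harnesses use 5 subjects × 45 trials with
2 chains × 500 over 10 seeds per scenario; forest suites use a few
hundred to a few thousand synthetic trials.  The `full` preset mirrors
the emulated study (34 subjects, 3 × 3000).  All randomness flows from
explicit seeds; identical seeds give bit-identical trial tables, draws
and fold assignments.  Degenerate inputs fail fast: empty or
constant-RT data, missing cells for a factor map, single-class
classification targets, fewer groups than folds.

## Known limitations

* AIC's blindness to subject-level complexity (above) means AIC-based
  selection between nested hierarchical models of different granularity
  should be read together with ΔELPD, as the comparison table does.
* The likelihood assumes no inter-trial parameter variability; recovery
  results say nothing about misspecification robustness.
* PPC quantile discrepancies at small per-cell trial counts are
  dominated by observation noise in the tail quantiles; the planted-
  misfit test uses a thin-tailed regime where a 0.1-second effect is
  resolvable.
* The truncation-normalizer approximation in the hierarchy would bias
  group-sd estimates if the population pressed against a constraint
  boundary (e.g. `z` near 0 or 1).
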