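# ruleddm

Hierarchical Bayesian drift-diffusion modelling and random-forest
importance analysis of how external task difficulty and intrinsic
learning shape two-choice decision performance.

The package targets a within-subject design that crosses **rule
hierarchy** — the number of nested conditional rules a trial requires
(1–3), the external-difficulty factor — with **block** (1–5), successive
task segments that proxy practice and learning.  Trial-level behaviour
(reaction time and accuracy) is decomposed with the drift-diffusion
model (DDM): noisy evidence accumulates at drift rate `v` from starting
point `Z0 = z·a` toward boundaries 0 and `a`, and observed RT is the
first-passage time plus a non-decision offset `t0`.  Because the
behavioural data the design emulates are not shareable, the package
ships a faithful synthetic-data generator and validates every stage —
estimation, diagnostics, model comparison, feature engineering,
forests — against known ground truth.

It is organised as an analysis project: the library under
`src/ruleddm/` holds all computation, the numbered drivers under
`analysis/` narrate the pipeline, and `tests/` pins the behaviour.

## What it computes

1. **Synthetic cohorts** (`design`, `simulate`) — the 5 × 3 × 6 trial
   design (90 trials/participant), DDM parameter populations defaulting
   to the published group posterior means, an Euler–Maruyama forward
   simulator with Brownian-bridge crossing correction, and the
   40-collected / 6-excluded / 34-retained screening fixture.
2. **Behavioural statistics** (`behavior`) — participant exclusions, RT
   trimming, the 3 × 5 repeated-measures ANOVA with Greenhouse–Geisser
   correction and partial eta squared, Bonferroni pairwise comparisons.
3. **Hierarchical Bayesian DDM** (`wfpt`, `models`, `sampler`) — the
   Wiener first-passage-time likelihood (accuracy-coded, dual series
   expansion) under four factor maps (hierarchy-only, block-only,
   additive, cell-wise), estimated by adaptive random-walk
   Metropolis–Hastings (3 chains, step adaptation toward 0.30 acceptance
   every 200 iterations, frozen after burn-in) with Gelman–Rubin
   diagnostics, highest-density intervals and posterior predictive
   checks.
4. **Model comparison** (`compare`) — AIC/BIC at plug-in posterior
   means, PSIS-LOO ELPD with the `ΔELPD > 2·se` rule (se from pointwise
   differences), and the selection logic.
5. **Random forests** (`features`, `forest`) — the 11-feature trial
   table with leakage-safe cumulative-moving-average history features,
   from-scratch CART forests (Gini / variance-reduction, depth ≤ 10,
   leaf ≥ 5, bootstrap + OOB), grouped 5-fold cross-validation at the
   participant level, 50-repeat OOB permutation importance, and the
   Top-8 vs full-feature comparison.

`docs/methods.md` documents the model, priors, sampler moves, numerical
choices and known limitations.

## Worked example

```python
from ruleddm import design, simulate, sampler

# ground truth: the published hierarchy-level posterior means
pop = design.hierarchy_population()          # v 0.92/0.60/0.38, a 2.98/5.17/6.36, ...
des = design.generate_design(n_participants=10, trials_per_cell=6, seed=11)
params = design.draw_subject_params(pop, 10, seed=12)
trials = simulate.simulate_dataset(des, params, seed=13)   # 900 trials

fit = sampler.fit(trials, 1, sampler.McmcConfig(n_chains=3, n_iter=1500,
                                                burn_in=750, seed=42))
print(f"max R-hat {fit.max_rhat:.3f}; "
      f"acceptance {fit.post_burn_acceptance:.3f}")
for p, c, truth in [("v", "h1", 0.92), ("a", "h3", 6.36), ("z", "h2", 0.18)]:
    d = fit.group_coef_draws(p, c)
    lo, hi = sampler.hdi(d)
    print(f"{p}[{c}]: mean {d.mean():.3f}, 95% HDI [{lo:.3f}, {hi:.3f}], "
          f"truth {truth}")
```

Output from this exact run:

```
max R-hat 1.025; acceptance 0.321
v[h1]: mean 0.904, 95% HDI [0.767, 1.054], truth 0.92
a[h3]: mean 6.347, 95% HDI [5.994, 6.706], truth 6.36
z[h2]: mean 0.199, 95% HDI [0.168, 0.229], truth 0.18
```

The sampler converges (R-hat < 1.05), its post-burn-in acceptance sits
in the 0.25–0.35 band the adaptation targets, and each generating value
lies inside its 95% HDI with the posterior mean within 15% — the
package's core recovery guarantee.

The full pipeline (simulate → preprocess → ANOVA → fit ×4 → compare →
PPC → features → forests) runs as numbered scripts:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_behavioral.py
python analysis/03_fit_models.py --scale desk
python analysis/04_model_comparison.py
python analysis/05_ppc.py
python analysis/06_forest.py
```

or in one step via the CLI: `ruleddm run-all --scale desk --seed 1`.

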