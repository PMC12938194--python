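"""Shared fixtures: all data is generated programmatically at test time.

The expensive fixtures (the parameter-recovery fit, the model-selection
harness) are session-scoped so the acceptance tests and the module tests
share one computation.
"""

from __future__ import annotations

import warnings

import pytest

from ruleddm import compare as mc, design, sampler, simulate


@pytest.fixture(scope="session")
def recovery_data():
    """10 subjects x 90 trials generated at the published hierarchy-level
    posterior means (the Model 1 ground truth of the recovery study)."""
    pop = design.hierarchy_population()
    des = design.generate_design(10, 6, seed=11)
    params = design.draw_subject_params(pop, 10, seed=12)
    trials = simulate.simulate_dataset(des, params, seed=13)
    return trials, pop


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """Model 1 fit of the recovery dataset (3 chains x 1500, 750 burn-in)."""
    trials, _ = recovery_data
    cfg = sampler.McmcConfig(n_chains=3, n_iter=1500, burn_in=750, seed=42)
    return sampler.fit(trials, 1, cfg)


@pytest.fixture(scope="session")
def tiny_trials():
    """5 subjects x 45 trials for cheap structural tests."""
    pop = design.hierarchy_population()
    des = design.generate_design(5, 3, seed=31)
    params = design.draw_subject_params(pop, 5, seed=32)
    return simulate.simulate_dataset(des, params, seed=33)


@pytest.fixture(scope="session")
def tiny_fit(tiny_trials):
    cfg = sampler.McmcConfig(n_chains=2, n_iter=400, burn_in=200, seed=7)
    return sampler.fit(tiny_trials, 1, cfg)


def harness_dataset(scenario: str, seed: int, n_subj: int = 5, tpc: int = 3):
    """One synthetic dataset of a planted scenario (interaction or null)."""
    if scenario == "interaction":
        pop = design.additive_population(v_interaction=0.1)
    elif scenario == "null":
        pop = design.hierarchy_population()
    else:
        raise ValueError(scenario)
    des = design.generate_design(n_subj, tpc, seed=seed * 13 + 1)
    params = design.draw_subject_params(pop, n_subj, seed=seed * 13 + 2)
    return simulate.simulate_dataset(des, params, seed=seed * 13 + 3)


def harness_compare(scenario: str, seed: int, n_iter: int = 500,
                    burn: int = 250, chains: int = 2):
    """Fit all four models to one harness dataset and compare them."""
    trials = harness_dataset(scenario, seed)
    fits = {}
    for mid in (1, 2, 3, 4):
        fits[mid] = sampler.fit(
            trials, mid,
            sampler.McmcConfig(chains, n_iter, burn, seed=seed * 13 + 4 + mid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mc.compare(fits, trials)


@pytest.fixture(scope="session")
def selection_harness():
    """Four-model comparisons over 10 seeded datasets per scenario."""
    return {scenario: [harness_compare(scenario, seed) for seed in range(10)]
            for scenario in ("interaction", "null")}
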