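"""Diagnostics (R-hat, HDI) and structural properties of the MCMC fit."""

import numpy as np
import pytest

from ruleddm import sampler
from ruleddm.design import PARAMS
from ruleddm.models import model_spec


class TestGelmanRubin:
    def test_null_case_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 2000))
        assert abs(sampler.gelman_rubin(chains) - 1.0) < 0.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert sampler.gelman_rubin(chains) > 1.1

    def test_manual_arithmetic_example(self):
        # two chains of four draws, every quantity computed by hand:
        # chain variances are both 5/3, W = 5/3; chain means 2.5 and 3.5,
        # B/n = var([2.5, 3.5]) = 0.5; var_hat = 3/4 * 5/3 + 0.5 = 1.75;
        # R-hat = sqrt(1.75 / (5/3)) = sqrt(1.05)
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        assert sampler.gelman_rubin(chains) == pytest.approx(np.sqrt(1.05))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            sampler.gelman_rubin(np.zeros((1, 100)))


class TestHdi:
    def test_constant_vector_degenerate(self):
        lo, hi = sampler.hdi(np.full(50, 3.2))
        assert (lo, hi) == (3.2, 3.2)

    def test_standard_normal_quantile_oracle(self):
        rng = np.random.default_rng(3)
        lo, hi = sampler.hdi(rng.normal(size=100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_uniform_interval_length(self):
        rng = np.random.default_rng(4)
        lo, hi = sampler.hdi(rng.uniform(size=100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_agrees_with_arviz(self):
        import arviz as az
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 1.0, size=20_000)
        lo, hi = sampler.hdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sampler.hdi(np.array([]))
        with pytest.raises(ValueError):
            sampler.hdi(np.ones(30), mass=1.5)


class TestHdiSignificant:
    def test_identical_samples_not_significant(self):
        x = np.random.default_rng(0).normal(size=500)
        assert sampler.hdi_significant(x, x) is False

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 500)
        b = rng.normal(10, 0.1, 500)
        assert sampler.hdi_significant(a, b) is True
        assert sampler.hdi_significant(b, a) is True  # symmetric

    def test_touching_intervals_count_as_overlap(self):
        # two-point masses make the HDIs exactly [0, 1] and [1, 2]:
        # the shared endpoint must count as overlap
        a = np.repeat([0.0, 1.0], 50)
        b = np.repeat([1.0, 2.0], 50)
        assert sampler.hdi(a) == (0.0, 1.0)
        assert sampler.hdi(b) == (1.0, 2.0)
        assert sampler.hdi_significant(a, b) is False


class TestFitStructure:
    def test_deterministic_under_seed(self, tiny_trials):
        cfg = sampler.McmcConfig(n_chains=2, n_iter=120, burn_in=60, seed=99)
        f1 = sampler.fit(tiny_trials, 1, cfg)
        f2 = sampler.fit(tiny_trials, 1, cfg)
        np.testing.assert_array_equal(f1.mu_draws, f2.mu_draws)
        np.testing.assert_array_equal(f1.subject_draws, f2.subject_draws)
        np.testing.assert_array_equal(f1.pointwise_loglik, f2.pointwise_loglik)

    def test_retained_draws_respect_constraints(self, tiny_fit):
        spec = tiny_fit.spec
        for pi, p in enumerate(PARAMS):
            mu = tiny_fit.mu_draws[:, :, pi, :]
            lo, hi = sampler.MU_BOUNDS[p]
            assert (mu > lo).all() and (mu < hi).all()
            sd = tiny_fit.sd_draws[:, :, pi, :]
            assert (sd > 0).all() and (sd <= sampler.SD_UPPER[p]).all()
        # subject-level cell values in the admissible region
        sub = tiny_fit.subject_draws  # (chains, kept, S, 4, k)
        cells = np.einsum("cdspk,lk->cdspl", sub, spec.X)
        assert (cells[:, :, :, 1, :] > 0.1).all()          # a
        assert ((cells[:, :, :, 3, :] > 0) &
                (cells[:, :, :, 3, :] < 1)).all()          # z
        assert (cells[:, :, :, 2, :] > 0).all()            # t0

    def test_pointwise_loglik_dimensions(self, tiny_fit, tiny_trials):
        chains, kept, n = tiny_fit.pointwise_loglik.shape
        assert chains == tiny_fit.cfg.n_chains
        assert kept == tiny_fit.cfg.n_iter - tiny_fit.cfg.burn_in
        assert n == len(tiny_trials)
        assert np.isfinite(tiny_fit.pointwise_loglik).all()

    def test_interaction_contrast_exactly_zero_for_hierarchy_only_model(self, tiny_fit):
        # a hierarchy-only factor map cannot express a block-varying gap
        mean, (lo, hi), draws = sampler.interaction_contrast(tiny_fit, "v")
        assert np.allclose(draws, 0.0, atol=1e-12)

    def test_empty_and_degenerate_data_rejected(self, tiny_trials):
        import pandas as pd
        cfg = sampler.McmcConfig(n_chains=2, n_iter=40, burn_in=20, seed=1)
        with pytest.raises(ValueError):
            sampler.fit(tiny_trials.iloc[:0], 1, cfg)
        const = tiny_trials.copy()
        const["rt"] = 1.0
        with pytest.raises(ValueError):
            sampler.fit(const, 1, cfg)

    def test_missing_cells_rejected(self, tiny_trials):
        # drop every block-1 trial: the cell-wise model has empty cells
        cfg = sampler.McmcConfig(n_chains=2, n_iter=40, burn_in=20, seed=1)
        partial = tiny_trials[tiny_trials["block"] > 1]
        with pytest.raises(ValueError):
            sampler.fit(partial, 4, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            sampler.McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            sampler.McmcConfig(target_accept=1.5)


def test_count_free_params_match_model_space():
    assert [4 * model_spec(m).k for m in (1, 2, 3, 4)] == [12, 20, 28, 60]
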