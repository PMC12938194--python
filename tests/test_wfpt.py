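"""WFPT density and log-likelihood against analytic and simulation oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from ruleddm import simulate, wfpt


def _integral(v, a, t0, z, boundary, upper_t=300.0):
    return quad(lambda t: wfpt.wfpt_density(t, v, a, t0, z, boundary),
                t0, upper_t, limit=400)[0]


class TestDensity:
    def test_symmetry_zero_drift_centered_start(self):
        ts = np.linspace(0.35, 3.0, 40)
        up = wfpt.wfpt_density(ts, 0.0, 1.5, 0.3, 0.5, "upper")
        lo = wfpt.wfpt_density(ts, 0.0, 1.5, 0.3, 0.5, "lower")
        np.testing.assert_allclose(up, lo, rtol=1e-9)

    def test_zero_below_t0(self):
        assert wfpt.wfpt_density(0.2, 1.0, 1.5, 0.3, 0.5) == 0.0
        assert wfpt.wfpt_density(0.3, 1.0, 1.5, 0.3, 0.5) == 0.0

    @pytest.mark.parametrize("v,a,z", [(0.92, 2.98, 0.29), (0.60, 5.17, 0.18),
                                       (-0.5, 1.2, 0.6), (0.0, 2.0, 0.35)])
    def test_integral_equals_absorption_probability(self, v, a, z):
        # numeric quadrature of the upper-boundary density vs the closed
        # form (1 - exp(-2 v a z)) / (1 - exp(-2 v a))
        got = _integral(v, a, 0.3, z, "upper")
        want = wfpt.absorption_probability(v, a, z)
        assert got == pytest.approx(want, abs=1e-4)

    def test_joint_integral_is_one_for_random_parameters(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            v = rng.uniform(-1.5, 1.5)
            a = rng.uniform(0.5, 4.0)
            z = rng.uniform(0.15, 0.85)
            total = _integral(v, a, 0.2, z, "upper") + \
                _integral(v, a, 0.2, z, "lower")
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_continuity_at_series_switch(self):
        # locate the scaled time where the term-count rule flips between
        # the small-time and large-time representations, then check the
        # density is continuous across it
        v, a, z, eps = 0.5, 1.8, 0.45, 1e-7

        def branch(tt):
            # independent re-derivation of the switch rule
            kl = math.sqrt(-2 * math.log(math.pi * tt * eps) /
                           (math.pi ** 2 * tt)) if math.pi * tt * eps < 1 else 0
            kl = max(kl, 1 / (math.pi * math.sqrt(tt)))
            ks = 2 + math.sqrt(-2 * tt * math.log(2 * eps * math.sqrt(2 * math.pi * tt))) \
                if 2 * math.sqrt(2 * math.pi * tt) * eps < 1 else 2
            ks = max(ks, math.sqrt(tt) + 1)
            return ks < kl

        lo_tt, hi_tt = 1e-3, 5.0
        assert branch(lo_tt) and not branch(hi_tt)
        for _ in range(60):
            mid = 0.5 * (lo_tt + hi_tt)
            if branch(mid):
                lo_tt = mid
            else:
                hi_tt = mid
        t_star = lo_tt * a * a
        f_lo = wfpt.wfpt_density(t_star * (1 - 1e-9) + 0.0, v, a, 0.0, z)
        f_hi = wfpt.wfpt_density(t_star * (1 + 1e-9), v, a, 0.0, z)
        assert abs(f_hi - f_lo) / f_lo < 1e-6

    def test_density_matches_simulation_histogram(self):
        # fine-dt forward simulation vs the analytic density on 20 bins
        v, a, t0, z = 1.2, 1.5, 0.3, 0.45
        n = 200_000
        rts, accs = simulate.simulate_cell(n, v, a, t0, z, dt=1e-4, seed=5)
        up_rts = rts[accs == 1]
        edges = np.quantile(up_rts, np.linspace(0, 1, 21))
        edges[0], edges[-1] = t0, np.inf
        obs, _ = np.histogram(up_rts, bins=edges)
        for i in range(20):
            hi = edges[i + 1] if np.isfinite(edges[i + 1]) else 60.0
            p_bin = quad(lambda t: wfpt.wfpt_density(t, v, a, t0, z, "upper"),
                         edges[i], hi, limit=200)[0]
            exp_n = n * p_bin
            # binomial noise: allow 4.5 sigma per bin (20 bins tested)
            assert abs(obs[i] - exp_n) < 4.5 * math.sqrt(exp_n) + 1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            wfpt.wfpt_density(1.0, np.nan, 1.5, 0.3, 0.5)
        with pytest.raises(ValueError):
            wfpt.wfpt_density(1.0, 1.0, 1.5, 0.3, 0.5, boundary="sideways")
        with pytest.raises(ValueError):
            wfpt.wfpt_density(1.0, 1.0, 1.5, 0.3, 0.5, eps=0.0)


class TestLoglik:
    def test_single_trial_equals_log_density(self):
        params = {"v": 0.8, "a": 2.0, "t0": 0.4, "z": 0.4}
        ll = wfpt.loglik({"rt": [1.1], "accuracy": [1]}, params)
        assert ll == pytest.approx(
            np.log(wfpt.wfpt_density(1.1, 0.8, 2.0, 0.4, 0.4, "upper")))
        ll0 = wfpt.loglik({"rt": [1.1], "accuracy": [0]}, params)
        assert ll0 == pytest.approx(
            np.log(wfpt.wfpt_density(1.1, 0.8, 2.0, 0.4, 0.4, "lower")))

    def test_additivity_under_duplication(self, tiny_trials):
        params = {"v": 0.6, "a": 3.0, "t0": 0.5, "z": 0.3}
        once = wfpt.loglik(tiny_trials, params)
        import pandas as pd
        twice = wfpt.loglik(pd.concat([tiny_trials, tiny_trials]), params)
        assert twice == pytest.approx(2 * once, rel=1e-12)

    def test_empty_slice_scores_zero(self):
        assert wfpt.loglik({"rt": [], "accuracy": []},
                           {"v": 1, "a": 2, "t0": 0.3, "z": 0.5}) == 0.0

    def test_rt_below_t0_floored_not_infinite(self):
        ll = wfpt.loglik({"rt": [0.2], "accuracy": [1]},
                         {"v": 1, "a": 2, "t0": 0.5, "z": 0.5})
        assert ll == wfpt.LOG_FLOOR

    def test_grid_search_mle_near_generating_drift(self):
        # 1-D grid-search oracle over v on a 5000-trial simulated cell
        v_true, a, t0, z = 0.9, 2.0, 0.4, 0.4
        rts, accs = simulate.simulate_cell(5000, v_true, a, t0, z, seed=21)
        grid = np.linspace(0.0, 2.0, 81)
        lls = [wfpt.loglik({"rt": rts, "accuracy": accs},
                           {"v": v, "a": a, "t0": t0, "z": z}) for v in grid]
        v_hat = grid[int(np.argmax(lls))]
        assert abs(v_hat - v_true) < 0.1
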