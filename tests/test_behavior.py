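"""Preprocessing and the repeated-measures ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ruleddm import behavior, design


def _trials_from_cell_means(values, rt=False):
    """One trial per participant x cell carrying the cell mean directly."""
    rows = []
    for s in range(values.shape[0]):
        idx = 0
        for h in range(3):
            for b in range(5):
                idx += 1
                v = values[s, h, b]
                rows.append((s + 1, b + 1, h + 1, idx, 0,
                             v if rt else 1.0, 1 if not rt else 1))
    df = pd.DataFrame(rows, columns=["participant_id", "block",
                                     "rule_hierarchy", "trial_index",
                                     "rule_switch", "rt", "accuracy"])
    if not rt:
        df["accuracy"] = values.reshape(-1)  # row order is (subject, h, b)
    return df


class TestPreprocess:
    def test_default_fixture_retains_34(self, recovery_data):
        trials, _ = recovery_data
        # 40-participant cohort: reuse the fixture's exclusion structure
        des = design.generate_design(40, 1, seed=1)
        des["rt"] = 1.0
        des["accuracy"] = 1
        fx = design.make_exclusion_fixture(seed=2)
        clean = behavior.preprocess(des, fx)
        assert clean.n_participants == 34
        assert len(clean.exclusion_log) == 6
        assert set(clean.exclusion_log["reason"]) == {"learning_accuracy", "protocol"}
        assert (clean.exclusion_log["reason"] == "learning_accuracy").sum() == 5

    def test_no_failures_all_retained(self, tiny_trials):
        fx = pd.DataFrame({
            "participant_id": sorted(tiny_trials["participant_id"].unique()),
            "learning_accuracy": 0.95,
            "hierarchical_response_ok": 1})
        clean = behavior.preprocess(tiny_trials, fx)
        assert clean.n_participants == tiny_trials["participant_id"].nunique()
        assert clean.exclusion_log.empty

    def test_short_rt_trial_removed(self, tiny_trials):
        doctored = tiny_trials.copy()
        doctored.loc[doctored.index[0], "rt"] = 0.05  # 50 ms, below the floor
        clean = behavior.preprocess(doctored)
        assert len(clean.trials) == len(doctored) - len(clean.outlier_log)
        low = clean.outlier_log[clean.outlier_log["bound"] == "low"]
        assert len(low) == 1
        assert low.iloc[0]["trial_index"] == doctored.iloc[0]["trial_index"]

    def test_incomplete_flags_rejected(self, tiny_trials):
        fx = pd.DataFrame({"participant_id": [1], "learning_accuracy": [0.9],
                           "hierarchical_response_ok": [1]})
        with pytest.raises(ValueError):
            behavior.preprocess(tiny_trials, fx)


class TestRmAnova:
    def test_constant_dv_gives_zero_f(self):
        vals = np.full((6, 3, 5), 0.8)
        res = behavior.rm_anova(_trials_from_cell_means(vals), dv="accuracy")
        assert (res.table["F"] == 0).all()

    def test_brute_force_ss_oracle(self):
        # 4 subjects, additive construction; sums of squares recomputed
        # here by direct definition over the marginal means
        rng = np.random.default_rng(8)
        Y = (0.5 + 0.1 * np.arange(3)[None, :, None]
             + 0.05 * np.arange(5)[None, None, :]
             + rng.normal(0, 0.05, (4, 1, 1))
             + rng.normal(0, 0.02, (4, 3, 5)))
        res = behavior.rm_anova(_trials_from_cell_means(Y), dv="accuracy")
        n, A, B = Y.shape
        m = Y.mean()
        m_a = Y.mean(axis=(0, 2))
        ss_a = 0.0
        for a in range(A):
            ss_a += n * B * (m_a[a] - m) ** 2
        ss_ea = 0.0
        for s in range(n):
            for a in range(A):
                ss_ea += B * (Y[s, a].mean() - Y[s].mean() - m_a[a] + m) ** 2
        row = res.table.set_index("effect").loc["hierarchy"]
        assert row["ss_effect"] == pytest.approx(ss_a, rel=1e-9)
        assert row["ss_error"] == pytest.approx(ss_ea, rel=1e-9)
        F_manual = (ss_a / (A - 1)) / (ss_ea / ((n - 1) * (A - 1)))
        assert row["F"] == pytest.approx(F_manual, rel=1e-9)
        assert row["eta_p2"] == pytest.approx(ss_a / (ss_a + ss_ea), rel=1e-9)

    def test_ss_decomposition_and_epsilon_ranges(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(0.7, 0.1, (8, 3, 5))
        res = behavior.rm_anova(_trials_from_cell_means(Y), dv="accuracy")
        t = res.table.set_index("effect")
        # total within-subject SS decomposes into the six components
        total_within = ((Y - Y.mean(axis=(1, 2), keepdims=True)) ** 2).sum()
        parts = t["ss_effect"].sum() + t["ss_error"].sum()
        assert parts == pytest.approx(total_within, rel=1e-9)
        for effect, levels in (("hierarchy", 3), ("block", 5)):
            eps = t.loc[effect, "gg_epsilon"]
            assert 1.0 / (levels - 1) < eps <= 1.0
            # GG shrinks numerator and denominator dfs by the same factor
            assert t.loc[effect, "df1_gg"] / t.loc[effect, "df1"] == \
                pytest.approx(t.loc[effect, "df2_gg"] / t.loc[effect, "df2"])

    def test_agrees_with_pingouin(self):
        rng = np.random.default_rng(10)
        Y = (0.6 + 0.08 * np.arange(3)[None, :, None]
             + rng.normal(0, 0.05, (10, 3, 5)))
        trials = _trials_from_cell_means(Y)
        res = behavior.rm_anova(trials, dv="accuracy").table.set_index("effect")
        import pingouin as pg
        agg = behavior.cell_aggregate(trials, dv="accuracy")
        ref = pg.rm_anova(data=agg, dv="value",
                          within=["rule_hierarchy", "block"],
                          subject="participant_id", detailed=True)
        ref_f = dict(zip(["hierarchy", "block", "interaction"], ref["F"][:3]))
        for effect in ("hierarchy", "block", "interaction"):
            assert res.loc[effect, "F"] == pytest.approx(ref_f[effect], rel=1e-6)

    def test_planted_hierarchy_effect_power(self):
        # means 0.9 / 0.8 / 0.7, noise sd 0.02, n = 20: detected in >= 9/10
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Y = (np.array([0.9, 0.8, 0.7])[None, :, None]
                 + rng.normal(0, 0.02, (20, 3, 5)))
            res = behavior.rm_anova(_trials_from_cell_means(Y), dv="accuracy")
            p = res.table.set_index("effect").loc["hierarchy", "p_gg"]
            hits += p < 0.001
        assert hits >= 9

    def test_missing_cells_rejected(self, tiny_trials):
        partial = tiny_trials[~((tiny_trials["participant_id"] == 1)
                                & (tiny_trials["block"] == 2))]
        with pytest.raises(ValueError):
            behavior.rm_anova(partial, dv="accuracy")


class TestPairwise:
    def test_identical_levels_not_significant(self):
        vals = np.broadcast_to(0.8, (10, 3, 5)).copy()
        rng = np.random.default_rng(2)
        vals = vals + rng.normal(0, 0.01, vals.shape)
        pw = behavior.pairwise(_trials_from_cell_means(vals), "hierarchy",
                               dv="accuracy")
        assert not pw["significant"].any()

    def test_planted_ordering_all_pairs_significant(self):
        rng = np.random.default_rng(3)
        Y = (np.array([0.9, 0.8, 0.7])[None, :, None]
             + rng.normal(0, 0.01, (12, 3, 5)))
        pw = behavior.pairwise(_trials_from_cell_means(Y), "hierarchy",
                               dv="accuracy")
        assert pw["significant"].all()
        assert len(pw) == 3
        # H1 > H2 > H3 ordering reflected in the mean differences
        assert (pw["mean_diff"] > 0).all()

    def test_antisymmetry(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        Y = rng.normal(0.7, 0.1, (8, 3, 5))
        trials = _trials_from_cell_means(Y)
        pw = behavior.pairwise(trials, "hierarchy", dv="accuracy")
        agg = behavior.cell_aggregate(trials, dv="accuracy")
        lv = agg.groupby(["participant_id", "rule_hierarchy"])["value"] \
            .mean().unstack()
        for _, row in pw.iterrows():
            t_rev, _ = stats.ttest_rel(lv[row["level_b"]], lv[row["level_a"]])
            assert t_rev == pytest.approx(-row["t"], rel=1e-12)

    def test_invalid_factor(self, tiny_trials):
        with pytest.raises(ValueError):
            behavior.pairwise(tiny_trials, "colour")
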