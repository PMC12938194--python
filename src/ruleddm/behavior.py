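"""Preprocessing and the 3 x 5 two-way repeated-measures ANOVA.

Participant exclusions (learning-phase accuracy < 0.80 or failure to
respond hierarchically) are applied before trial-level RT trimming.  The
trimming rule — drop trials with RT < 0.2 s or above the participant x
cell mean + 3 sd, in a single pass — is a conventional choice, logged per
trial.  The ANOVA operates on participant x cell aggregates (mean
accuracy; mean correct RT), reports Greenhouse-Geisser-corrected degrees
of freedom and partial eta squared, and pairwise comparisons use paired
t-tests with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["CleanDataset", "preprocess", "rm_anova", "pairwise",
           "cell_aggregate", "AnovaResult", "RT_FLOOR"]

RT_FLOOR = 0.2     # seconds
RT_SD_MULT = 3.0

FACTORS = {"hierarchy": "rule_hierarchy", "block": "block"}


@dataclass
class CleanDataset:
    trials: pd.DataFrame
    exclusion_log: pd.DataFrame   # participant_id, reason
    outlier_log: pd.DataFrame     # participant_id, trial_index, bound

    @property
    def n_participants(self) -> int:
        return self.trials["participant_id"].nunique()


def preprocess(raw: pd.DataFrame, fixture_flags: pd.DataFrame | None = None) -> CleanDataset:
    """Apply participant exclusions, then RT-outlier trimming.

    ``fixture_flags`` carries per-participant screening results
    (``learning_accuracy``, ``hierarchical_response_ok``); ``None`` means
    no participant is excluded.  Deterministic; every removed record is
    accounted for in the logs.
    """
    excl_rows = []
    trials = raw
    if fixture_flags is not None:
        flagged = set(raw["participant_id"].unique())
        have = set(fixture_flags["participant_id"])
        if not flagged <= have:
            raise ValueError("fixture flags must cover all participants in the data")
        for _, r in fixture_flags.iterrows():
            if r["hierarchical_response_ok"] == 0:
                excl_rows.append((r["participant_id"], "protocol"))
            elif r["learning_accuracy"] < 0.80:
                excl_rows.append((r["participant_id"], "learning_accuracy"))
        excluded = {p for p, _ in excl_rows}
        trials = raw[~raw["participant_id"].isin(excluded)]
    exclusion_log = pd.DataFrame(excl_rows, columns=["participant_id", "reason"])

    # single-pass RT trimming on the retained participants
    stats_ = trials.groupby(["participant_id", "block", "rule_hierarchy"])["rt"] \
        .agg(["mean", "std"]).rename(columns={"mean": "m", "std": "s"})
    merged = trials.merge(stats_, left_on=["participant_id", "block", "rule_hierarchy"],
                          right_index=True, how="left")
    upper = merged["m"] + RT_SD_MULT * merged["s"].fillna(np.inf)
    low = merged["rt"] < RT_FLOOR
    high = merged["rt"] > upper
    out_rows = []
    for mask, bound in ((low, "low"), (high, "high")):
        for _, r in merged.loc[mask].iterrows():
            out_rows.append((r["participant_id"], r["trial_index"], bound))
    outlier_log = pd.DataFrame(out_rows, columns=["participant_id", "trial_index",
                                                  "bound"])
    clean = trials.loc[~(low | high).to_numpy()].reset_index(drop=True)
    return CleanDataset(trials=clean, exclusion_log=exclusion_log,
                        outlier_log=outlier_log)


def cell_aggregate(trials: pd.DataFrame, dv: str = "accuracy") -> pd.DataFrame:
    """Participant x cell means: mean accuracy, or mean RT of correct trials."""
    if dv == "accuracy":
        g = trials.groupby(["participant_id", "rule_hierarchy", "block"])["accuracy"] \
            .mean()
    elif dv == "rt":
        correct = trials[trials["accuracy"] == 1]
        g = correct.groupby(["participant_id", "rule_hierarchy", "block"])["rt"].mean()
    else:
        raise ValueError("dv must be 'accuracy' or 'rt'")
    return g.rename("value").reset_index()


@dataclass
class AnovaResult:
    table: pd.DataFrame     # per effect: F, df, GG epsilon & dfs, p, eta_p2
    dv: str

    def __str__(self):
        return f"Repeated-measures ANOVA on {self.dv}\n" + self.table.to_string(index=False)


def _gg_epsilon(scores: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject scores and an orthonormal contrast."""
    Y = scores @ C.T
    S = np.cov(Y, rowvar=False)
    S = np.atleast_2d(S)
    d = C.shape[0]
    tr = np.trace(S)
    denom = d * np.trace(S @ S)
    if denom <= 1e-24:   # degenerate (constant) scores
        return 1.0
    return float(tr * tr / denom)


def rm_anova(data: CleanDataset | pd.DataFrame, dv: str = "accuracy") -> AnovaResult:
    """Two-way (hierarchy x block) within-subject ANOVA on cell aggregates.

    Requires a complete, balanced participant x 3 x 5 grid of cell means
    (trials are aggregated first).  For each effect reports the F ratio,
    uncorrected and Greenhouse-Geisser-corrected degrees of freedom (the
    same epsilon shrinks numerator and denominator), the GG-corrected
    p-value, and partial eta squared ``SS_effect / (SS_effect + SS_error)``.
    """
    trials = data.trials if isinstance(data, CleanDataset) else data
    agg = cell_aggregate(trials, dv=dv)
    grid = agg.pivot_table(index="participant_id", columns=["rule_hierarchy", "block"],
                           values="value")
    if grid.isna().any().any() or grid.shape[1] != 15:
        raise ValueError("need a complete participant x hierarchy x block grid "
                         f"(got shape {grid.shape} with "
                         f"{int(grid.isna().sum().sum())} missing cells)")
    A, B = 3, 5
    Y = grid.to_numpy().reshape(-1, A, B)  # (n, hierarchy, block)
    n = Y.shape[0]

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * B * np.sum((m_a - m) ** 2)
    ss_ea = B * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_b = n * A * np.sum((m_b - m) ** 2)
    ss_eb = A * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - m)
    ss_eab = np.sum(resid ** 2)

    Ca = linalg.helmert(A)
    Cb = linalg.helmert(B)
    Cab = np.kron(Ca, Cb)
    eps = {
        "hierarchy": _gg_epsilon(Y.mean(axis=2), Ca),
        "block": _gg_epsilon(Y.mean(axis=1), Cb),
        "interaction": _gg_epsilon(Y.reshape(n, A * B), Cab),
    }

    rows = []
    for name, ss_eff, ss_err, df1, df2 in (
            ("hierarchy", ss_a, ss_ea, A - 1, (n - 1) * (A - 1)),
            ("block", ss_b, ss_eb, B - 1, (n - 1) * (B - 1)),
            ("interaction", ss_ab, ss_eab, (A - 1) * (B - 1),
             (n - 1) * (A - 1) * (B - 1))):
        tiny = 1e-12 * (np.abs(Y).max() ** 2 + 1.0) * Y.size
        if ss_eff < tiny and ss_err < tiny:   # constant dv: no variation
            ss_eff = ss_err = 0.0
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        e = min(eps[name], 1.0)
        p = float(stats.f.sf(F, df1 * e, df2 * e)) if ms_err > 0 else 1.0
        rows.append({"effect": name, "F": F, "df1": df1, "df2": df2,
                     "gg_epsilon": e, "df1_gg": df1 * e, "df2_gg": df2 * e,
                     "p_gg": p, "ss_effect": ss_eff, "ss_error": ss_err,
                     "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0})
    return AnovaResult(table=pd.DataFrame(rows), dv=dv)


def pairwise(data: CleanDataset | pd.DataFrame, factor: str = "hierarchy",
             dv: str = "accuracy", correction: str = "bonferroni") -> pd.DataFrame:
    """Paired comparisons of factor-level means with adjusted p-values."""
    if factor not in FACTORS:
        raise ValueError("factor must be 'hierarchy' or 'block'")
    trials = data.trials if isinstance(data, CleanDataset) else data
    agg = cell_aggregate(trials, dv=dv)
    col = FACTORS[factor]
    lv = agg.groupby(["participant_id", col])["value"].mean().unstack()
    pairs = list(combinations(lv.columns, 2))
    rows = []
    for a, b in pairs:
        d = lv[a] - lv[b]
        t, p = stats.ttest_rel(lv[a], lv[b])
        p_adj = min(1.0, p * len(pairs)) if correction == "bonferroni" else p
        rows.append({"level_a": a, "level_b": b, "mean_diff": float(d.mean()),
                     "t": float(t), "p": float(p), "p_adj": float(p_adj),
                     "significant": p_adj < 0.05})
    return pd.DataFrame(rows)
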