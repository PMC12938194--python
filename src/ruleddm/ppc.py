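"""Posterior predictive checks: re-simulate at posterior means, compare
per-cell accuracy and RT quantiles against the observed data."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CELL_BLOCK, CELL_HIER, N_CELLS, cell_index
from .sampler import FitResult, RHAT_WARN
from .simulate import simulate_cell

__all__ = ["posterior_predictive_check", "PpcReport"]

log = logging.getLogger(__name__)

QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class PpcReport:
    table: pd.DataFrame          # per-cell observed vs simulated summaries
    max_rt_discrepancy: float    # max |observed - simulated| RT quantile (s)
    median_rt_discrepancy: float

    def __str__(self):
        return (f"PPC: max RT-quantile discrepancy "
                f"{self.max_rt_discrepancy:.3f} s, median "
                f"{self.median_rt_discrepancy:.3f} s over "
                f"{self.table.shape[0]} cells")


def posterior_predictive_check(fitres: FitResult, data: pd.DataFrame,
                               seed: int = 0, n_sim_per_trial: int = 5,
                               params_override: np.ndarray | None = None) -> PpcReport:
    """Simulate replicate data at posterior means and compare to observations.

    For each participant x cell with observed trials, simulates
    ``n_sim_per_trial`` times as many trials at that subject's
    posterior-mean parameters, then reports observed vs simulated accuracy
    and RT quantiles pooled per design cell.  Cells with no observed
    trials are skipped with a logged warning.  ``params_override`` (same
    shape as ``FitResult.subject_cell_means()``) substitutes the
    parameters, which is useful for planted-misfit checks.
    """
    if fitres.max_rhat >= RHAT_WARN:
        log.warning("PPC on a fit with max R-hat %.3f >= %.2f",
                    fitres.max_rhat, RHAT_WARN)
    vals = params_override if params_override is not None \
        else fitres.subject_cell_means()
    cells = cell_index(data["block"].to_numpy(), data["rule_hierarchy"].to_numpy())
    pid_arr = data["participant_id"].to_numpy()
    rng = np.random.default_rng(seed)

    obs_rt = {c: [] for c in range(N_CELLS)}
    sim_rt = {c: [] for c in range(N_CELLS)}
    obs_acc = {c: [] for c in range(N_CELLS)}
    sim_acc = {c: [] for c in range(N_CELLS)}
    for si, pid in enumerate(fitres.participant_ids):
        for c in range(N_CELLS):
            m = (pid_arr == pid) & (cells == c)
            n = int(m.sum())
            if n == 0:
                log.warning("participant %s cell %d has no trials; skipped", pid, c)
                continue
            v, a, t0, z = (float(vals[si, p, c]) for p in range(4))
            rts, accs = simulate_cell(n * n_sim_per_trial, v, a, t0, z,
                                      seed=int(rng.integers(2**31)))
            obs_rt[c].append(data.loc[m, "rt"].to_numpy())
            obs_acc[c].append(data.loc[m, "accuracy"].to_numpy())
            sim_rt[c].append(rts)
            sim_acc[c].append(accs)

    rows = []
    for c in range(N_CELLS):
        if not obs_rt[c]:
            continue
        o_rt = np.concatenate(obs_rt[c])
        s_rt = np.concatenate(sim_rt[c])
        o_q = np.quantile(o_rt, QUANTILES)
        s_q = np.quantile(s_rt, QUANTILES)
        rows.append({
            "block": CELL_BLOCK[c], "hierarchy": CELL_HIER[c],
            "obs_accuracy": float(np.concatenate(obs_acc[c]).mean()),
            "sim_accuracy": float(np.concatenate(sim_acc[c]).mean()),
            **{f"obs_rt_q{int(q*100)}": oq for q, oq in zip(QUANTILES, o_q)},
            **{f"sim_rt_q{int(q*100)}": sq for q, sq in zip(QUANTILES, s_q)},
            "max_abs_rt_q_diff": float(np.max(np.abs(o_q - s_q))),
        })
    table = pd.DataFrame(rows)
    diffs = table["max_abs_rt_q_diff"].to_numpy()
    return PpcReport(table=table,
                     max_rt_discrepancy=float(diffs.max()),
                     median_rt_discrepancy=float(np.median(diffs)))
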