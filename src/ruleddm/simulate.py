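"""Forward simulation of the drift-diffusion process (Euler-Maruyama).

Evidence starts at ``z * a`` and evolves as ``dx = v dt + sqrt(dt) dW``
(diffusion coefficient fixed at 1) until it crosses 0 or ``a``.  The upper
boundary codes a correct response; observed RT is ``t0`` plus the
first-passage time.  Trials that fail to absorb within the per-trial time
cap are resampled, so every emitted trial has a genuine crossing.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .design import cell_index

__all__ = ["simulate_dataset", "simulate_cell", "DEFAULT_DT", "DEFAULT_T_MAX"]

DEFAULT_DT = 0.001
# Cap long enough that even slow-drift / wide-boundary cells (mean FPT of
# several seconds at the default generating values) absorb almost surely;
# capped trials are resampled.
DEFAULT_T_MAX = 60.0


@njit(cache=True)
def _sim_trials(n: int, v: float, a: float, t0: float, z: float,
                dt: float, t_max: float, seed: int):
    np.random.seed(seed)
    rts = np.empty(n)
    accs = np.empty(n, dtype=np.int64)
    sqdt = math.sqrt(dt)
    max_steps = int(t_max / dt)
    for i in range(n):
        while True:
            x = z * a
            hit = -1
            for step in range(1, max_steps + 1):
                xp = x
                x += v * dt + sqdt * np.random.normal()
                if x >= a:
                    hit = 1
                    break
                if x <= 0.0:
                    hit = 0
                    break
                # Brownian-bridge correction: the path may have crossed a
                # boundary between grid points even though both endpoints
                # are interior; without it the crossing rate is biased
                # by O(sqrt(dt)).
                if np.random.random() < math.exp(-2.0 * (a - xp) * (a - x) / dt):
                    hit = 1
                    break
                if np.random.random() < math.exp(-2.0 * xp * x / dt):
                    hit = 0
                    break
            if hit >= 0:
                rts[i] = t0 + step * dt
                accs[i] = hit
                break
            # no absorption within the cap: resample the trial
    return rts, accs


def simulate_cell(n: int, v: float, a: float, t0: float, z: float,
                  dt: float = DEFAULT_DT, t_max: float = DEFAULT_T_MAX,
                  seed: int = 0):
    """Simulate ``n`` i.i.d. trials of one parameter cell.

    Returns ``(rts, accuracies)``; accuracy 1 codes upper-boundary
    absorption.  Reproducible under ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (a > 0.1 and 0 < z < 1 and t0 >= 0):
        raise ValueError(f"inadmissible parameters (v={v}, a={a}, t0={t0}, z={z})")
    return _sim_trials(int(n), float(v), float(a), float(t0), float(z),
                       float(dt), float(t_max), int(seed) & 0x7FFFFFFF)


def simulate_dataset(design: pd.DataFrame, subject_params: np.ndarray,
                     dt: float = DEFAULT_DT, t_max: float = DEFAULT_T_MAX,
                     seed: int = 0) -> pd.DataFrame:
    """Attach simulated (rt, accuracy) to every trial of a design.

    ``subject_params`` has shape ``(n_participants, 4, 15)`` in PARAMS
    order (see :func:`ruleddm.design.draw_subject_params`); participant ids
    in the design must be 1..n_participants.  Each participant x cell slice
    is simulated with its own seed derived from ``seed`` so the output is
    reproducible and independent of trial ordering.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pids = np.sort(design["participant_id"].unique())
    if subject_params.shape[0] < pids.size or subject_params.shape[1:] != (4, 15):
        raise ValueError("subject_params must cover every participant with a (4, 15) slice")
    out = design.copy()
    out["rt"] = np.nan
    out["accuracy"] = -1
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(pids.size * 15 * 2).reshape(pids.size, 15, 2)
    cells = cell_index(design["block"].to_numpy(), design["rule_hierarchy"].to_numpy())
    for si, pid in enumerate(pids):
        for c in range(15):
            mask = (design["participant_id"].to_numpy() == pid) & (cells == c)
            n = int(mask.sum())
            if n == 0:
                continue
            v, a, t0, z = (float(subject_params[si, pi, c]) for pi in range(4))
            if not (a > 0.1 and 0 < z < 1):
                raise ValueError(f"missing or inadmissible parameters for participant "
                                 f"{pid}, cell {c}")
            rts, accs = simulate_cell(n, v, a, t0, z, dt=dt, t_max=t_max,
                                      seed=int(cell_seeds[si, c, 0] & 0x7FFFFFFF))
            out.loc[mask, "rt"] = rts
            out.loc[mask, "accuracy"] = accs
    out["accuracy"] = out["accuracy"].astype(int)
    return out


def mean_fpt(v: float, a: float, z: float) -> float:
    """Analytic mean first-passage time (either boundary), diffusion 1."""
    x0 = z * a
    if abs(v) < 1e-9:
        return x0 * (a - x0)
    return (a / v) * (-np.expm1(-2 * v * x0)) / (-np.expm1(-2 * v * a)) - x0 / v
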