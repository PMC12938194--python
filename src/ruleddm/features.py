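"""Trial-level feature table for the random-forest analysis.

Eleven features per trial, in three groups:

* experimental design — ``Block_ID``, ``Rule_Hierarchy`` and their product
  term ``Block_ID*Rule_Hierarchy``;
* model parameters — the subject x cell posterior means ``v, a, t0, Z0``
  broadcast to the trials of that cell, plus ``Rhat`` (mean convergence
  index of the four parameters for that cell); the start proportion z is
  deliberately absent because it is Z0 / a and would duplicate information
  already carried by Z0 and a;
* history — cumulative moving averages of past accuracy
  (``Acc_CMA_AllPast``) and past log RT (``RT_CMA_AllPast``), and the rule
  switch flag ``Rule_alt``.

The CMA columns are strictly causal: the value at trial t is the mean of
trials 1..t-1 of the same participant only.  Trial 1, which has no
history, takes a neutral initialiser (0.5 for accuracy; for RT a supplied
constant, typically the training-fold median log RT so that grouped
cross-validation stays leakage-free).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import cell_index
from .sampler import FitResult

__all__ = ["FEATURE_COLUMNS", "build_features", "running_mean_past",
           "ACC_CMA_INIT"]

FEATURE_COLUMNS = [
    "Block_ID", "Rule_Hierarchy", "Block_ID*Rule_Hierarchy",
    "v", "a", "t0", "Z0", "Rhat",
    "Acc_CMA_AllPast", "RT_CMA_AllPast", "Rule_alt",
]

ACC_CMA_INIT = 0.5


def running_mean_past(x: np.ndarray, init: float) -> np.ndarray:
    """Mean of x[0..t-1] at position t; ``init`` at t = 0."""
    out = np.empty(len(x), dtype=float)
    out[0] = init
    if len(x) > 1:
        out[1:] = np.cumsum(x)[:-1] / np.arange(1, len(x))
    return out


def _cell_rhat(fitres: FitResult) -> np.ndarray:
    """Mean group-level R-hat of the four DDM parameters per design cell."""
    from .design import PARAMS
    out = np.zeros(15)
    for c in range(15):
        vals = []
        for pi, p in enumerate(PARAMS):
            # R-hat of the coefficients this cell loads on, weighted by X
            w = fitres.spec.X[c]
            rh = np.array([fitres.rhat[f"mu_{p}[{n}]"]
                           for n in fitres.spec.coef_names])
            vals.append(np.abs(w) @ rh / np.abs(w).sum())
        out[c] = np.mean(vals)
    return out


def build_features(trials: pd.DataFrame, fitres: FitResult,
                   rt_cma_init: float | None = None) -> pd.DataFrame:
    """Assemble the 11-feature table aligned to trials.

    ``fitres`` supplies participant x cell posterior-mean DDM parameters
    and the per-cell convergence index.  ``rt_cma_init`` seeds the first
    trial's RT history; if None, the median log RT of ``trials`` is used
    (pass the training-fold value to preserve the leakage guarantee under
    cross-validation; the provenance is recorded in ``attrs``).

    Returns a DataFrame with the 11 feature columns plus ``participant_id``
    (the grouping key), ``Accuracy`` and ``log_rt`` targets.
    """
    trials = trials.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
    pids = trials["participant_id"].to_numpy()
    cells = cell_index(trials["block"].to_numpy(),
                       trials["rule_hierarchy"].to_numpy())
    fit_pids = list(fitres.participant_ids)
    missing = set(np.unique(pids)) - set(fit_pids)
    if missing:
        raise ValueError(f"fit does not cover participants {sorted(missing)}")
    sidx = np.array([fit_pids.index(p) for p in pids])

    vals = fitres.subject_cell_means()   # (S, 4, 15)
    rhat_cell = _cell_rhat(fitres)

    init_src = "supplied"
    if rt_cma_init is None:
        rt_cma_init = float(np.median(np.log(trials["rt"].to_numpy())))
        init_src = "global_median"

    out = pd.DataFrame({
        "participant_id": pids,
        "Block_ID": trials["block"].to_numpy(),
        "Rule_Hierarchy": trials["rule_hierarchy"].to_numpy(),
    })
    out["Block_ID*Rule_Hierarchy"] = out["Block_ID"] * out["Rule_Hierarchy"]
    out["v"] = vals[sidx, 0, cells]
    out["a"] = vals[sidx, 1, cells]
    out["t0"] = vals[sidx, 2, cells]
    out["Z0"] = vals[sidx, 3, cells] * vals[sidx, 1, cells]  # z * a
    out["Rhat"] = rhat_cell[cells]

    acc = trials["accuracy"].to_numpy(dtype=float)
    logrt = np.log(trials["rt"].to_numpy(dtype=float))
    acc_cma = np.empty(len(trials))
    rt_cma = np.empty(len(trials))
    for pid in np.unique(pids):
        m = pids == pid
        acc_cma[m] = running_mean_past(acc[m], ACC_CMA_INIT)
        rt_cma[m] = running_mean_past(logrt[m], rt_cma_init)
    out["Acc_CMA_AllPast"] = acc_cma
    out["RT_CMA_AllPast"] = rt_cma
    out["Rule_alt"] = trials["rule_switch"].to_numpy()

    out["Accuracy"] = trials["accuracy"].to_numpy()
    out["log_rt"] = logrt
    out.attrs["rt_cma_init"] = rt_cma_init
    out.attrs["rt_cma_init_provenance"] = init_src
    assert list(out.columns[1:12]) == FEATURE_COLUMNS
    return out
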