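"""Model comparison: AIC, BIC, PSIS-LOO ELPD and the delta-ELPD rule.

The plug-in log-likelihood for AIC/BIC is the total accuracy-coded WFPT
log-likelihood evaluated with every subject's parameters at their
posterior means (group-level structure enters through ``k``, the count of
free group-level location parameters).  ELPD_loo is importance-sampling
leave-one-out with Pareto-smoothed weights computed from the pointwise
log-likelihood draws; the standard error of a pairwise ELPD difference is
taken from the pointwise differences, never from the two standard errors
in quadrature.  Two models differ meaningfully when
``delta ELPD > 2 * se(delta)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import count_free_params
from .sampler import FitResult, RHAT_WARN

__all__ = ["aic", "bic", "elpd_loo", "compare", "ComparisonTable"]

PARETO_K_WARN = 0.7


def aic(fitres: FitResult, k: int | None = None,
        trials: pd.DataFrame | None = None, loglik_hat: float | None = None) -> float:
    """Akaike information criterion, ``2k - 2 logL`` at the plug-in fit.

    ``k`` counts free group-level location parameters; the plug-in logL is
    the total log-likelihood at subject posterior means.  Note that in a
    hierarchical model this penalty does not price subject-level
    flexibility, so AIC systematically flatters the cell-wise model — the
    predictive comparison (:func:`elpd_loo`) is the complexity-honest
    companion metric.
    """
    k = count_free_params(fitres.spec) if k is None else k
    if loglik_hat is None:
        loglik_hat = fitres.loglik_at_posterior_means(trials, level="subject")
    return float(2 * k - 2 * loglik_hat)


def bic(fitres: FitResult, n_trials: int, k: int | None = None,
        trials: pd.DataFrame | None = None, loglik_hat: float | None = None) -> float:
    """Bayesian information criterion, ``k ln(n) - 2 logL``."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    k = count_free_params(fitres.spec) if k is None else k
    if loglik_hat is None:
        loglik_hat = fitres.loglik_at_posterior_means(trials, level="subject")
    return float(k * np.log(n_trials) - 2 * loglik_hat)


def elpd_loo(fitres: FitResult, pointwise: bool = False):
    """PSIS-LOO expected log predictive density from the posterior draws.

    Returns ``(elpd, se)``; with ``pointwise=True`` also the per-trial
    elpd contributions and Pareto k-hat diagnostics.  k-hat above 0.7 for
    any trial triggers a reliability warning (the value is still returned).
    """
    ll = fitres.pointwise_loglik  # (chains, draws, trials)
    if ll.shape[0] * ll.shape[1] < 100:
        raise ValueError("need at least 100 retained draws for LOO")
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(
            posterior={"mu": fitres.mu_draws.reshape(ll.shape[0], ll.shape[1], -1)},
            log_likelihood={"obs": ll})
        res = az.loo(idata, pointwise=True)
    khat = np.asarray(res.pareto_k)
    n_bad = int((khat > PARETO_K_WARN).sum())
    if n_bad:
        warnings.warn(f"PSIS-LOO: {n_bad} trial(s) with Pareto k-hat > "
                      f"{PARETO_K_WARN}; ELPD may be unreliable")
    elpd = float(res.elpd_loo)
    se = float(res.se)
    if pointwise:
        return elpd, se, np.asarray(res.loo_i), khat
    return elpd, se


@dataclass
class ComparisonTable:
    per_model: pd.DataFrame   # k, aic, bic, max_rhat, elpd_loo, elpd_se
    pairwise: pd.DataFrame    # delta ELPD with se from pointwise diffs
    selected: int             # lowest AIC among converged models

    def __str__(self):
        lines = ["Model comparison", self.per_model.to_string(index=False), "",
                 "Pairwise delta ELPD (better - worse)",
                 self.pairwise.to_string(index=False),
                 f"\nSelected model: {self.selected} (lowest AIC among converged)"]
        return "\n".join(lines)


def compare(fits: dict[int, FitResult], data: pd.DataFrame) -> ComparisonTable:
    """Fill the four-model comparison table and apply the selection logic.

    All fits must be on the identical trial set.  Selection is the lowest
    AIC among converged models (max R-hat < 1.05); every model pair also
    gets a delta-ELPD significance flag (``|delta| > 2 se(delta)``).
    """
    n = len(data)
    sizes = {mid: f.pointwise_loglik.shape[-1] for mid, f in fits.items()}
    if len(set(sizes.values())) != 1 or next(iter(sizes.values())) != n:
        raise ValueError(f"fits cover mismatched trial sets: {sizes} vs n={n}")

    rows, loo_pw = [], {}
    for mid in sorted(fits):
        f = fits[mid]
        k = count_free_params(f.spec)
        ll_hat = f.loglik_at_posterior_means(data, level="subject")
        e, se, pw, _ = elpd_loo(f, pointwise=True)
        loo_pw[mid] = pw
        rows.append({"model": mid, "k": k,
                     "aic": aic(f, k=k, loglik_hat=ll_hat),
                     "bic": bic(f, n, k=k, loglik_hat=ll_hat),
                     "max_rhat": f.max_rhat,
                     "elpd_loo": e, "elpd_se": se})
    per_model = pd.DataFrame(rows)

    pw_rows = []
    mids = sorted(fits)
    for i, m1 in enumerate(mids):
        for m2 in mids[i + 1:]:
            d = loo_pw[m1] - loo_pw[m2]
            delta = float(d.sum())
            se_d = float(np.sqrt(d.size) * d.std(ddof=1)) if d.size > 1 else 0.0
            better, worse = (m1, m2) if delta >= 0 else (m2, m1)
            pw_rows.append({"better": better, "worse": worse,
                            "delta_elpd": abs(delta), "se_delta": se_d,
                            "significant": abs(delta) > 2 * se_d})
    pairwise = pd.DataFrame(pw_rows)

    converged = per_model[per_model["max_rhat"] < RHAT_WARN]
    pool = converged if len(converged) else per_model
    selected = int(pool.loc[pool["aic"].idxmin(), "model"])
    return ComparisonTable(per_model=per_model, pairwise=pairwise,
                           selected=selected)
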