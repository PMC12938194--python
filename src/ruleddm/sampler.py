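"""Hierarchical Bayesian estimation of any model spec by adaptive RW-MH.

Model structure
---------------
For each DDM parameter p in (v, a, t0, z) and each coefficient j of the
model's factor map, subject-level coefficients are drawn from a group
Normal, ``beta[s, p, j] ~ N(mu[p, j], sigma[p, j])``, truncated to the
admissible region (a > 0.1, z in (0, 1), t0 > 0; enforced by rejection).
Hyperpriors are uniform on bounded supports.  A subject's cell parameters
are ``X @ beta[s, p]`` and trials are scored with the accuracy-coded WFPT
likelihood.

Sampling is component-wise Gaussian random walk on unconstrained scales
(identity for v, log for a and the group sds, logit for z, range-logit for
t0; identity for Model 3's effect-coded block offsets).  Every
``adapt_window`` iterations during burn-in each component's step size is
multiplied by ``exp(+-0.1)`` to steer its local acceptance toward the
target (0.30 by default); after burn-in the kernel is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
from numba import njit

from . import wfpt
from .design import N_CELLS, PARAMS, cell_index
from .models import ModelSpec, model_spec

__all__ = ["McmcConfig", "FitResult", "fit", "gelman_rubin", "hdi",
           "hdi_significant", "interaction_contrast"]

# transform codes
T_IDENTITY, T_LOG, T_LOGIT, T_RLOGIT = 0, 1, 2, 3

# uniform hyperprior supports for group means, per DDM parameter (one-hot
# coefficients); offsets get the symmetric ranges below
MU_BOUNDS = {"v": (-5.0, 5.0), "a": (0.1, 10.0), "t0": (0.01, 3.0),
             "z": (0.01, 0.99)}
# group sds uniform on (0, half the mean range]
SD_UPPER = {p: 0.5 * (hi - lo) for p, (lo, hi) in MU_BOUNDS.items()}
# subject-level hard constraints on one-hot coefficients (natural scale)
SUBJ_BOUNDS = {"v": (-np.inf, np.inf), "a": (0.1, np.inf),
               "t0": (0.0, np.inf), "z": (0.0, 1.0)}
TRANSFORMS = {"v": T_IDENTITY, "a": T_LOG, "z": T_LOGIT, "t0": T_RLOGIT}
RLOGIT_RANGE = MU_BOUNDS["t0"]

RHAT_WARN = 1.05    # the operative convergence criterion
RHAT_STRICT = 1.01  # stricter reference threshold


@dataclass
class McmcConfig:
    """Sampler settings (defaults follow the study's protocol)."""

    n_chains: int = 3
    n_iter: int = 3000
    burn_in: int = 1500
    adapt_window: int = 200
    target_accept: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("require 0 < burn_in < n_iter")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _t_fwd(x, tc, L, U):
    if tc == T_LOG:
        return math.log(x)
    if tc == T_LOGIT:
        return math.log(x / (1.0 - x))
    if tc == T_RLOGIT:
        u = (x - L) / (U - L)
        return math.log(u / (1.0 - u))
    return x


@njit(cache=True)
def _t_inv(p, tc, L, U):
    if tc == T_LOG:
        return math.exp(p)
    if tc == T_LOGIT:
        return 1.0 / (1.0 + math.exp(-p))
    if tc == T_RLOGIT:
        return L + (U - L) / (1.0 + math.exp(-p))
    return p


@njit(cache=True)
def _t_logjac(x, tc, L, U):
    if tc == T_LOG:
        return math.log(x)
    if tc == T_LOGIT:
        return math.log(x) + math.log(1.0 - x)
    if tc == T_RLOGIT:
        u = (x - L) / (U - L)
        return math.log(U - L) + math.log(u) + math.log(1.0 - u)
    return 0.0


@njit(cache=True)
def _cell_ll(rts, accs, i0, i1, v, a, t0, z, eps):
    return wfpt._slice_loglik(rts, accs, i0, i1, v, a, t0, z, eps)


@njit(cache=True)
def _run_chain(seed, n_iter, burn_in, adapt_window, target,
               X, tc, mu_lo, mu_hi, sd_hi, sb_lo, sb_hi,
               col_cells, col_ncells,
               rts, accs, ptr,
               mu, sigma, beta,
               step_mu, step_sd, step_b, step_sh, step_sc,
               eps):
    """One MCMC chain.  Arrays `mu, sigma (4,k)`, `beta (S,4,k)` are the
    initial state and are mutated in place.  Trials are pre-sorted by
    (subject, cell); ``ptr[s, c]..ptr[s, c+1]`` slices subject s, cell c.
    Returns retained draws, per-trial log-likelihoods (sorted trial order),
    and per-window acceptance rates.
    """
    np.random.seed(seed)
    S = beta.shape[0]
    k = X.shape[1]
    n_kept = n_iter - burn_in

    # cell-value cache and per-(subject, cell) log-likelihood cache
    val = np.empty((S, 4, N_CELLS))
    for s in range(S):
        for p in range(4):
            for c in range(N_CELLS):
                acc = 0.0
                for j in range(k):
                    acc += X[c, j] * beta[s, p, j]
                val[s, p, c] = acc
    cll = np.empty((S, N_CELLS))
    for s in range(S):
        for c in range(N_CELLS):
            cll[s, c] = _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                 val[s, 0, c], val[s, 1, c], val[s, 2, c],
                                 val[s, 3, c], eps)

    mu_draws = np.empty((n_kept, 4, k))
    sd_draws = np.empty((n_kept, 4, k))
    beta_draws = np.empty((n_kept, S, 4, k))
    ll_draws = np.empty((n_kept, rts.shape[0]))

    n_windows = (n_iter + adapt_window - 1) // adapt_window
    win_rates = np.zeros(n_windows)
    # per-component window accept/proposal counts
    acc_mu = np.zeros((4, k))
    acc_sd = np.zeros((4, k))
    acc_b = np.zeros((S, 4, k))
    acc_sh = np.zeros((4, k))
    acc_sc = np.zeros((4, k))
    prop_mu = np.zeros((4, k))
    prop_sd = np.zeros((4, k))
    prop_b = np.zeros((S, 4, k))
    prop_sh = np.zeros((4, k))
    prop_sc = np.zeros((4, k))
    win_prop = 0.0
    win_acc = 0.0
    win_i = 0
    n_hyper_rep = 3  # cheap conditional updates, repeated for mixing

    rl_lo = 0.0
    rl_hi = 0.0

    for it in range(1, n_iter + 1):
        for _rep in range(n_hyper_rep):
            # ---- group means ----
            for p in range(4):
                for j in range(k):
                    th = mu[p, j]
                    code = tc[p, j]
                    L = mu_lo[p, j]
                    U = mu_hi[p, j]
                    rl_lo, rl_hi = L, U
                    ph = _t_fwd(th, code, rl_lo, rl_hi) + step_mu[p, j] * np.random.normal()
                    thn = _t_inv(ph, code, rl_lo, rl_hi)
                    win_prop += 1.0
                    prop_mu[p, j] += 1.0
                    if thn <= L or thn >= U:
                        continue
                    s2 = sigma[p, j] * sigma[p, j]
                    d = 0.0
                    for s in range(S):
                        x = beta[s, p, j]
                        d += ((x - th) * (x - th) - (x - thn) * (x - thn)) / (2.0 * s2)
                    d += _t_logjac(thn, code, rl_lo, rl_hi) - _t_logjac(th, code, rl_lo, rl_hi)
                    if d >= 0.0 or np.random.random() < math.exp(d):
                        mu[p, j] = thn
                        acc_mu[p, j] += 1.0
                        win_acc += 1.0

            # ---- group sds ----
            for p in range(4):
                for j in range(k):
                    th = sigma[p, j]
                    ph = math.log(th) + step_sd[p, j] * np.random.normal()
                    thn = math.exp(ph)
                    win_prop += 1.0
                    prop_sd[p, j] += 1.0
                    if thn <= 0.0 or thn > sd_hi[p, j]:
                        continue
                    m = mu[p, j]
                    d = 0.0
                    for s in range(S):
                        x = beta[s, p, j]
                        d += (-math.log(thn) - (x - m) * (x - m) / (2.0 * thn * thn)) \
                            - (-math.log(th) - (x - m) * (x - m) / (2.0 * th * th))
                    d += math.log(thn) - math.log(th)  # log-Jacobian
                    if d >= 0.0 or np.random.random() < math.exp(d):
                        sigma[p, j] = thn
                        acc_sd[p, j] += 1.0
                        win_acc += 1.0

        # ---- joint shift: translate a group mean with all its subjects ----
        # The subject deviations x_s - mu are invariant, so the hierarchical
        # prior cancels and the move is limited only by the data likelihood;
        # it breaks the slow random walk of mu through its narrow
        # conditional given the subjects.
        for p in range(4):
            for j in range(k):
                delta = step_sh[p, j] * np.random.normal()
                win_prop += 1.0
                prop_sh[p, j] += 1.0
                mun = mu[p, j] + delta
                if mun <= mu_lo[p, j] or mun >= mu_hi[p, j]:
                    continue
                ok = True
                for s in range(S):
                    xn = beta[s, p, j] + delta
                    if xn <= sb_lo[p, j] or xn >= sb_hi[p, j]:
                        ok = False
                        break
                if not ok:
                    continue
                nc = col_ncells[j]
                d = 0.0
                for s in range(S):
                    for ci in range(nc):
                        c = col_cells[j, ci]
                        vv = val[s, 0, c]
                        aa = val[s, 1, c]
                        tt = val[s, 2, c]
                        zz = val[s, 3, c]
                        dd = X[c, j] * delta
                        if p == 0:
                            vv += dd
                        elif p == 1:
                            aa += dd
                        elif p == 2:
                            tt += dd
                        else:
                            zz += dd
                        d += _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                      vv, aa, tt, zz, eps) - cll[s, c]
                if d >= 0.0 or np.random.random() < math.exp(d):
                    mu[p, j] = mun
                    for s in range(S):
                        beta[s, p, j] += delta
                        for ci in range(nc):
                            c = col_cells[j, ci]
                            val[s, p, c] += X[c, j] * delta
                            cll[s, c] = _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                                 val[s, 0, c], val[s, 1, c],
                                                 val[s, 2, c], val[s, 3, c], eps)
                    acc_sh[p, j] += 1.0
                    win_acc += 1.0

        # ---- joint scale: rescale a group sd with its subject deviations ----
        # sigma' = sigma e^d, x_s' = mu + (x_s - mu) e^d keeps the
        # standardised residuals fixed; the hierarchical-prior change (-S d)
        # and the map's Jacobian ((S+1) d) reduce the log ratio to
        # delta-loglik + d.  This decouples sigma from the subjects and
        # breaks the funnel that otherwise stalls the group sds.
        for p in range(4):
            for j in range(k):
                dl = step_sc[p, j] * np.random.normal()
                win_prop += 1.0
                prop_sc[p, j] += 1.0
                sn = sigma[p, j] * math.exp(dl)
                if sn <= 1e-6 or sn > sd_hi[p, j]:
                    continue
                g = math.exp(dl)
                m = mu[p, j]
                ok = True
                for s in range(S):
                    xn = m + (beta[s, p, j] - m) * g
                    if xn <= sb_lo[p, j] or xn >= sb_hi[p, j]:
                        ok = False
                        break
                if not ok:
                    continue
                nc = col_ncells[j]
                d = dl
                for s in range(S):
                    dd0 = (beta[s, p, j] - m) * (g - 1.0)
                    for ci in range(nc):
                        c = col_cells[j, ci]
                        vv = val[s, 0, c]
                        aa = val[s, 1, c]
                        tt = val[s, 2, c]
                        zz = val[s, 3, c]
                        dd = X[c, j] * dd0
                        if p == 0:
                            vv += dd
                        elif p == 1:
                            aa += dd
                        elif p == 2:
                            tt += dd
                        else:
                            zz += dd
                        d += _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                      vv, aa, tt, zz, eps) - cll[s, c]
                if d >= 0.0 or np.random.random() < math.exp(d):
                    sigma[p, j] = sn
                    for s in range(S):
                        dd0 = (beta[s, p, j] - m) * (g - 1.0)
                        beta[s, p, j] += dd0
                        for ci in range(nc):
                            c = col_cells[j, ci]
                            val[s, p, c] += X[c, j] * dd0
                            cll[s, c] = _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                                 val[s, 0, c], val[s, 1, c],
                                                 val[s, 2, c], val[s, 3, c], eps)
                    acc_sc[p, j] += 1.0
                    win_acc += 1.0

        # ---- subject coefficients ----
        for s in range(S):
            for p in range(4):
                for j in range(k):
                    th = beta[s, p, j]
                    code = tc[p, j]
                    rl_lo, rl_hi = mu_lo[p, j], mu_hi[p, j]
                    ph = _t_fwd(th, code, rl_lo, rl_hi) + step_b[s, p, j] * np.random.normal()
                    thn = _t_inv(ph, code, rl_lo, rl_hi)
                    win_prop += 1.0
                    prop_b[s, p, j] += 1.0
                    if thn <= sb_lo[p, j] or thn >= sb_hi[p, j]:
                        continue
                    m = mu[p, j]
                    s2 = sigma[p, j] * sigma[p, j]
                    d = ((th - m) * (th - m) - (thn - m) * (thn - m)) / (2.0 * s2)
                    d += _t_logjac(thn, code, rl_lo, rl_hi) - _t_logjac(th, code, rl_lo, rl_hi)
                    # data term over affected cells
                    nc = col_ncells[j]
                    dll = 0.0
                    for ci in range(nc):
                        c = col_cells[j, ci]
                        vv = val[s, 0, c]
                        aa = val[s, 1, c]
                        tt = val[s, 2, c]
                        zz = val[s, 3, c]
                        delta = X[c, j] * (thn - th)
                        if p == 0:
                            vv += delta
                        elif p == 1:
                            aa += delta
                        elif p == 2:
                            tt += delta
                        else:
                            zz += delta
                        dll += _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                        vv, aa, tt, zz, eps) - cll[s, c]
                    d += dll
                    if d >= 0.0 or np.random.random() < math.exp(d):
                        beta[s, p, j] = thn
                        for ci in range(nc):
                            c = col_cells[j, ci]
                            delta = X[c, j] * (thn - th)
                            val[s, p, c] += delta
                            cll[s, c] = _cell_ll(rts, accs, ptr[s, c], ptr[s, c + 1],
                                                 val[s, 0, c], val[s, 1, c],
                                                 val[s, 2, c], val[s, 3, c], eps)
                        acc_b[s, p, j] += 1.0
                        win_acc += 1.0

        # ---- window bookkeeping / adaptation ----
        if it % adapt_window == 0 or it == n_iter:
            if win_prop > 0.0:
                win_rates[win_i] = win_acc / win_prop
            if it % adapt_window == 0 and it <= burn_in:
                for p in range(4):
                    for j in range(k):
                        if prop_mu[p, j] > 0:
                            step_mu[p, j] *= math.exp(
                                0.1 if acc_mu[p, j] / prop_mu[p, j] > target else -0.1)
                        if prop_sd[p, j] > 0:
                            step_sd[p, j] *= math.exp(
                                0.1 if acc_sd[p, j] / prop_sd[p, j] > target else -0.1)
                        if prop_sh[p, j] > 0:
                            step_sh[p, j] *= math.exp(
                                0.1 if acc_sh[p, j] / prop_sh[p, j] > target else -0.1)
                        if prop_sc[p, j] > 0:
                            step_sc[p, j] *= math.exp(
                                0.1 if acc_sc[p, j] / prop_sc[p, j] > target else -0.1)
                        for s in range(S):
                            if prop_b[s, p, j] > 0:
                                step_b[s, p, j] *= math.exp(
                                    0.1 if acc_b[s, p, j] / prop_b[s, p, j] > target else -0.1)
            if it % adapt_window == 0:
                acc_mu[:] = 0.0
                acc_sd[:] = 0.0
                acc_b[:] = 0.0
                acc_sh[:] = 0.0
                acc_sc[:] = 0.0
                prop_mu[:] = 0.0
                prop_sd[:] = 0.0
                prop_b[:] = 0.0
                prop_sh[:] = 0.0
                prop_sc[:] = 0.0
                win_acc = 0.0
                win_prop = 0.0
                win_i += 1

        # ---- record ----
        if it > burn_in:
            r = it - burn_in - 1
            mu_draws[r] = mu
            sd_draws[r] = sigma
            beta_draws[r] = beta
            for s in range(S):
                for c in range(N_CELLS):
                    for i in range(ptr[s, c], ptr[s, c + 1]):
                        ll_draws[r, i] = wfpt._trial_logpdf(
                            rts[i], accs[i], val[s, 0, c], val[s, 1, c],
                            val[s, 2, c], val[s, 3, c], eps)

    return mu_draws, sd_draws, beta_draws, ll_draws, win_rates[:win_i + 1]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws) -> float:
    """Classic Gelman-Rubin R-hat from an (n_chains, n_draws) array.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B/n the variance of the chain means.  Requires >= 2 chains with
    >= 2 retained draws each (in practice use far more).
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n_chains >= 2, n_draws) array")
    m, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 retained draws per chain")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def hdi(draws, mass: float = 0.95):
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def hdi_significant(draws_a, draws_b, mass: float = 0.95) -> bool:
    """True iff the two HDIs are disjoint (a shared endpoint counts as overlap)."""
    lo_a, hi_a = hdi(draws_a, mass)
    lo_b, hi_b = hdi(draws_b, mass)
    return bool(hi_a < lo_b or hi_b < lo_a)


# ---------------------------------------------------------------------------
# fit driver
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws and diagnostics of one hierarchical fit."""

    spec: ModelSpec
    cfg: McmcConfig
    participant_ids: np.ndarray
    mu_draws: np.ndarray        # (chains, kept, 4, k)
    sd_draws: np.ndarray        # (chains, kept, 4, k)
    subject_draws: np.ndarray   # (chains, kept, S, 4, k)
    pointwise_loglik: np.ndarray  # (chains, kept, n_trials) original trial order
    acceptance_history: np.ndarray  # (chains, n_windows)
    n_post_burn_windows: int
    rhat: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rhat:
            for pi, p in enumerate(PARAMS):
                for j, cname in enumerate(self.spec.coef_names):
                    self.rhat[f"mu_{p}[{cname}]"] = gelman_rubin(
                        self.mu_draws[:, :, pi, j])
                    self.rhat[f"sd_{p}[{cname}]"] = gelman_rubin(
                        self.sd_draws[:, :, pi, j])

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_WARN

    def group_coef_draws(self, param: str, coef: str) -> np.ndarray:
        """All post-burn-in draws of one group mean, pooled over chains."""
        pi = PARAMS.index(param)
        j = self.spec.coef_names.index(coef)
        return self.mu_draws[:, :, pi, j].ravel()

    def group_cell_mean(self, param: str) -> np.ndarray:
        """Posterior-mean group value per design cell (length 15)."""
        pi = PARAMS.index(param)
        beta_bar = self.mu_draws[:, :, pi, :].mean(axis=(0, 1))
        return self.spec.cell_values(beta_bar)

    def subject_cell_means(self) -> np.ndarray:
        """Posterior-mean subject parameters, shape (S, 4, 15)."""
        beta_bar = self.subject_draws.mean(axis=(0, 1))  # (S, 4, k)
        out = np.empty((beta_bar.shape[0], 4, N_CELLS))
        for p in range(4):
            out[:, p, :] = beta_bar[:, p, :] @ self.spec.X.T
        return out

    @property
    def post_burn_acceptance(self) -> float:
        """Mean acceptance rate over post-burn-in adaptation windows."""
        tail = self.acceptance_history[:, -self.n_post_burn_windows:]
        return float(tail.mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for pi, p in enumerate(PARAMS):
            for j, cname in enumerate(self.spec.coef_names):
                d = self.mu_draws[:, :, pi, j].ravel()
                lo, hi = hdi(d)
                rows.append((f"mu_{p}[{cname}]", d.mean(), d.std(), lo, hi,
                             self.rhat[f"mu_{p}[{cname}]"]))
                d = self.sd_draws[:, :, pi, j].ravel()
                lo, hi = hdi(d)
                rows.append((f"sd_{p}[{cname}]", d.mean(), d.std(), lo, hi,
                             self.rhat[f"sd_{p}[{cname}]"]))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "hdi_2.5%", "hdi_97.5%", "rhat"])

    def draws_long(self) -> pd.DataFrame:
        """Group-level draws in long format (chain, iteration, parameter, value)."""
        rows = []
        n_chains, n_kept = self.mu_draws.shape[:2]
        for ch in range(n_chains):
            for pi, p in enumerate(PARAMS):
                for j, cname in enumerate(self.spec.coef_names):
                    rows.append(pd.DataFrame({
                        "chain": ch,
                        "iteration": np.arange(n_kept),
                        "parameter": f"mu_{p}[{cname}]",
                        "value": self.mu_draws[ch, :, pi, j],
                    }))
        return pd.concat(rows, ignore_index=True)

    def loglik_at_posterior_means(self, trials: pd.DataFrame,
                                  level: str = "group") -> float:
        """Plug-in total log-likelihood at posterior-mean parameters.

        ``level="group"`` (default) applies the group-level posterior-mean
        cell values to every subject, so the implied free-parameter count
        is exactly the group-level ``k`` that AIC/BIC penalise.
        ``level="subject"`` plugs in each subject's own posterior means
        (more flexible, but its complexity is not captured by ``k``).
        """
        if level == "group":
            g = np.stack([self.group_cell_mean(p) for p in PARAMS])  # (4, 15)
            vals = np.broadcast_to(g, (len(self.participant_ids), 4, N_CELLS))
        elif level == "subject":
            vals = self.subject_cell_means()
        else:
            raise ValueError("level must be 'group' or 'subject'")
        cells = cell_index(trials["block"].to_numpy(),
                           trials["rule_hierarchy"].to_numpy())
        total = 0.0
        for si, pid in enumerate(self.participant_ids):
            sel = trials["participant_id"].to_numpy() == pid
            for c in np.unique(cells[sel]):
                m = sel & (cells == c)
                total += wfpt.loglik(
                    {"rt": trials.loc[m, "rt"], "accuracy": trials.loc[m, "accuracy"]},
                    {"v": vals[si, 0, c], "a": vals[si, 1, c],
                     "t0": vals[si, 2, c], "z": vals[si, 3, c]})
        return float(total)


def _bounds_arrays(spec: ModelSpec):
    k = spec.k
    tc = np.empty((4, k), dtype=np.int64)
    mu_lo = np.empty((4, k))
    mu_hi = np.empty((4, k))
    sd_hi = np.empty((4, k))
    sb_lo = np.empty((4, k))
    sb_hi = np.empty((4, k))
    for pi, p in enumerate(PARAMS):
        lo, hi = MU_BOUNDS[p]
        half = 0.5 * (hi - lo)
        for j in range(k):
            sd_hi[pi, j] = SD_UPPER[p]
            if spec.is_offset[j]:
                tc[pi, j] = T_IDENTITY
                mu_lo[pi, j], mu_hi[pi, j] = -half, half
                sb_lo[pi, j], sb_hi[pi, j] = -np.inf, np.inf
            else:
                tc[pi, j] = TRANSFORMS[p]
                mu_lo[pi, j], mu_hi[pi, j] = lo, hi
                sb_lo[pi, j], sb_hi[pi, j] = SUBJ_BOUNDS[p]
                if tc[pi, j] == T_RLOGIT:
                    # range-logit keeps proposals inside the prior support
                    sb_lo[pi, j] = max(sb_lo[pi, j], lo)
                    sb_hi[pi, j] = min(sb_hi[pi, j], hi)
    return tc, mu_lo, mu_hi, sd_hi, sb_lo, sb_hi


_INIT_SIGMA = {"v": 0.2, "a": 0.3, "t0": 0.1, "z": 0.05}
_STEP_MU = {"v": 0.15, "a": 0.10, "t0": 0.15, "z": 0.25}
_STEP_SUBJ = {"v": 0.30, "a": 0.15, "t0": 0.30, "z": 0.50}


def _init_state(spec: ModelSpec, rng, S, min_rt_subj_col, tc, mu_lo, mu_hi):
    """Moderately over-dispersed chain initialisation (data-informed for t0)."""
    k = spec.k
    mu = np.empty((4, k))
    sigma = np.empty((4, k))
    beta = np.empty((S, 4, k))
    step_mu = np.empty((4, k))
    step_sd = np.full((4, k), 0.4)
    step_b = np.empty((S, 4, k))
    # natural-scale shift steps, roughly the data-information scale
    step_sh = np.empty((4, k))
    step_sc = np.full((4, k), 0.4)  # log-scale sigma moves
    sh0 = {"v": 0.08, "a": 0.15, "t0": 0.03, "z": 0.03}
    init_lo = {"v": 0.0, "a": 1.5, "z": 0.15}
    init_hi = {"v": 1.2, "a": 7.0, "z": 0.45}
    # Subject random-walk steps scale with the information a coefficient
    # receives: fewer design cells per column (e.g. the cell-wise model)
    # means a flatter conditional, so proportionally larger steps keep the
    # burn-in adaptation within reach of the target acceptance.
    ncov = np.abs(spec.X).astype(bool).sum(axis=0)
    col_scale = np.sqrt(5.0 / np.maximum(ncov, 1))
    for pi, p in enumerate(PARAMS):
        for j in range(k):
            if spec.is_offset[j]:
                mu[pi, j] = rng.normal(0.0, 0.05)
                step_mu[pi, j] = 0.10
            elif p == "t0":
                m = min_rt_subj_col[:, j].min()
                mu[pi, j] = rng.uniform(0.3, 0.7) * min(m, MU_BOUNDS["t0"][1])
                mu[pi, j] = np.clip(mu[pi, j], 0.02, 2.9)
                step_mu[pi, j] = _STEP_MU[p]
            else:
                mu[pi, j] = rng.uniform(init_lo[p], init_hi[p])
                step_mu[pi, j] = _STEP_MU[p]
            sigma[pi, j] = _INIT_SIGMA[p] * rng.uniform(0.5, 1.5)
            base_step = _STEP_SUBJ[p] if not spec.is_offset[j] else 0.15
            step_b[:, pi, j] = base_step * col_scale[j]
            step_sh[pi, j] = sh0[p]
            for s in range(S):
                x = mu[pi, j] + rng.normal(0.0, 0.5 * sigma[pi, j])
                if not spec.is_offset[j]:
                    if p == "a":
                        x = max(x, 0.15)
                    elif p == "z":
                        x = float(np.clip(x, 0.05, 0.95))
                    elif p == "t0":
                        x = float(np.clip(min(x, 0.8 * min_rt_subj_col[s, j]),
                                          0.02, 2.9))
                beta[s, pi, j] = x
    return mu, sigma, beta, step_mu, step_sd, step_b, step_sh, step_sc


def fit(data: pd.DataFrame, spec: ModelSpec | int,
        cfg: McmcConfig | None = None) -> FitResult:
    """Fit one model of the four-model space to a trial table.

    ``data`` needs columns participant_id, block, rule_hierarchy, rt,
    accuracy.  Returns a :class:`FitResult` with per-chain post-burn-in
    draws, pointwise log-likelihoods, per-parameter R-hat and the
    adaptation acceptance history.  Fully reproducible under ``cfg.seed``.
    """
    if isinstance(spec, int):
        spec = model_spec(spec)
    cfg = cfg or McmcConfig()
    if len(data) == 0:
        raise ValueError("empty trial table")
    rt = data["rt"].to_numpy(dtype=float)
    if np.ptp(rt) == 0.0:
        raise ValueError("degenerate data: RT column is constant")
    acc = data["accuracy"].to_numpy(dtype=np.int64)
    pids = np.sort(data["participant_id"].unique())
    S = pids.size
    cells = cell_index(data["block"].to_numpy(), data["rule_hierarchy"].to_numpy())

    # affected-cell lists per design-matrix column
    k = spec.k
    col_cells = np.zeros((k, N_CELLS), dtype=np.int64)
    col_ncells = np.zeros(k, dtype=np.int64)
    for j in range(k):
        cs = np.where(spec.X[:, j] != 0)[0]
        col_ncells[j] = cs.size
        col_cells[j, :cs.size] = cs

    # sort trials by (subject, cell); build slice pointers
    sidx = np.searchsorted(pids, data["participant_id"].to_numpy())
    order = np.lexsort((cells, sidx))
    rts_s = np.ascontiguousarray(rt[order])
    accs_s = np.ascontiguousarray(acc[order])
    ptr = np.zeros((S, N_CELLS + 1), dtype=np.int64)
    for s in range(S):
        in_s = sidx[order] == s
        for c in range(N_CELLS + 1):
            ptr[s, c] = np.searchsorted(cells[order][in_s], c) + np.searchsorted(sidx[order], s)

    # every model coefficient must see at least one trial per participant
    for j in range(k):
        cs = col_cells[j, :col_ncells[j]]
        for s in range(S):
            if sum(ptr[s, c + 1] - ptr[s, c] for c in cs) == 0:
                raise ValueError(
                    f"participant {pids[s]} has no trials for model coefficient "
                    f"{spec.coef_names[j]!r}")

    tc, mu_lo, mu_hi, sd_hi, sb_lo, sb_hi = _bounds_arrays(spec)

    # per-subject, per-column minimum RT (for t0 initialisation)
    min_rt_subj_col = np.empty((S, k))
    for s in range(S):
        for j in range(k):
            cs = col_cells[j, :col_ncells[j]]
            m = np.inf
            for c in cs:
                if ptr[s, c + 1] > ptr[s, c]:
                    m = min(m, rts_s[ptr[s, c]:ptr[s, c + 1]].min())
            min_rt_subj_col[s, j] = m if np.isfinite(m) else 3.0

    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = [int(x & 0x7FFFFFFF) for x in ss.generate_state(cfg.n_chains)]
    init_rng = np.random.default_rng(ss.spawn(1)[0])

    mu_all, sd_all, beta_all, ll_all, win_all = [], [], [], [], []
    for ch in range(cfg.n_chains):
        mu, sigma, beta, step_mu, step_sd, step_b, step_sh, step_sc = _init_state(
            spec, init_rng, S, min_rt_subj_col, tc, mu_lo, mu_hi)
        md, sd_, bd, lld, wr = _run_chain(
            chain_seeds[ch], cfg.n_iter, cfg.burn_in, cfg.adapt_window,
            cfg.target_accept, spec.X, tc, mu_lo, mu_hi, sd_hi, sb_lo, sb_hi,
            col_cells, col_ncells, rts_s, accs_s, ptr,
            mu, sigma, beta, step_mu, step_sd, step_b, step_sh, step_sc,
            wfpt.DEFAULT_EPS)
        mu_all.append(md)
        sd_all.append(sd_)
        beta_all.append(bd)
        # scatter pointwise log-likelihoods back to the original trial order
        lld_orig = np.empty_like(lld)
        lld_orig[:, order] = lld
        ll_all.append(lld_orig)
        win_all.append(wr)

    n_win = min(len(w) for w in win_all)
    n_pb = max(1, (cfg.n_iter - cfg.burn_in) // cfg.adapt_window)
    return FitResult(
        spec=spec, cfg=cfg, participant_ids=pids,
        mu_draws=np.stack(mu_all), sd_draws=np.stack(sd_all),
        subject_draws=np.stack(beta_all),
        pointwise_loglik=np.stack(ll_all),
        acceptance_history=np.stack([w[:n_win] for w in win_all]),
        n_post_burn_windows=n_pb)


def interaction_contrast(fitres: FitResult, param: str = "v",
                         mass: float = 0.95):
    """Posterior summary of the hierarchy x block interaction strength.

    Defined (configurably, since the original scalar is not pinned down)
    as the mean over adjacent block pairs of the difference-of-differences
    of cell means across the extreme hierarchy levels, per posterior draw:
    ``mean_b [ (v[h3,b+1] - v[h1,b+1]) - (v[h3,b] - v[h1,b]) ]``.
    Returns (posterior mean, (hdi_lo, hdi_hi), draws).
    """
    pi = PARAMS.index(param)
    n_chains, n_kept = fitres.mu_draws.shape[:2]
    beta = fitres.mu_draws[:, :, pi, :].reshape(n_chains * n_kept, -1)
    cellv = beta @ fitres.spec.X.T  # (draws, 15)
    grid = cellv.reshape(-1, 5, 3)  # (draws, block, hierarchy)
    gap = grid[:, :, 2] - grid[:, :, 0]  # h3 - h1 per block
    contrast = np.diff(gap, axis=1).mean(axis=1)
    lo, hi = hdi(contrast, mass)
    return float(contrast.mean()), (lo, hi), contrast
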