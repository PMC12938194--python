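"""Wiener first-passage-time (WFPT) density and log-likelihood.

The drift-diffusion model describes a two-choice decision as a Wiener
process with drift ``v`` (evidence/s), diffusion coefficient 1, absorbing
boundaries at 0 and ``a`` (evidence units), and starting point
``Z0 = z * a`` where ``z`` is the start proportion in (0, 1).  A response
is emitted when the process first hits a boundary; observed reaction time
is the first-passage time plus a non-decision offset ``t0`` (s).

The density of the first-passage time at a named boundary is evaluated
with the classic pair of series expansions — a small-time representation
(sum over image charges) and a large-time representation (sine series) —
picking whichever needs fewer terms for the requested accuracy.  Fitting
is accuracy-coded: correct responses absorb at the upper boundary.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "wfpt_density",
    "absorption_probability",
    "loglik",
    "LOG_FLOOR",
]

#: Floor applied to per-trial log densities so that proposals violating the
#: t0 constraint (rt <= t0) or otherwise degenerate are heavily penalised
#: but remain finite for the sampler.
LOG_FLOOR = -700.0

DEFAULT_EPS = 1e-7


@njit(cache=True, fastmath=False)
def _fpt_std(tt: float, w: float, eps: float) -> float:
    """Standardised (a=1, v=0) lower-boundary FPT density at scaled time tt.

    Chooses between the small-time and large-time series using the
    term-count heuristic; both series are truncated so the neglected tail
    is below ``eps``.
    """
    if tt <= 0.0:
        return 0.0

    # number of terms needed by the large-time (sine) series
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    # number of terms needed by the small-time (image) series
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time representation
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time representation
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _wfpt_pdf(t: float, v: float, a: float, z: float, upper: bool, eps: float) -> float:
    """FPT density at decision time ``t`` (already net of t0) at one boundary."""
    if t <= 0.0 or a <= 0.0 or z <= 0.0 or z >= 1.0:
        return 0.0
    if upper:
        # reflect: upper-boundary density equals lower-boundary density
        # of the mirrored process
        v = -v
        w = 1.0 - z
    else:
        w = z
    tt = t / (a * a)
    f = _fpt_std(tt, w, eps)
    return f * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


@njit(cache=True)
def _trial_logpdf(rt: float, correct: int, v: float, a: float, t0: float, z: float,
                  eps: float) -> float:
    """Accuracy-coded per-trial log density with the LOG_FLOOR penalty."""
    if not (a > 0.1 and 0.0 < z < 1.0 and t0 > 0.0):
        return LOG_FLOOR
    if not (math.isfinite(v) and math.isfinite(a) and math.isfinite(t0) and math.isfinite(z)):
        return LOG_FLOOR
    td = rt - t0
    if td <= 0.0:
        return LOG_FLOOR
    d = _wfpt_pdf(td, v, a, z, correct == 1, eps)
    if d <= 0.0:
        return LOG_FLOOR
    lp = math.log(d)
    if lp < LOG_FLOOR:
        lp = LOG_FLOOR
    return lp


@njit(cache=True)
def _slice_loglik(rts, accs, i0: int, i1: int, v: float, a: float, t0: float,
                  z: float, eps: float) -> float:
    s = 0.0
    for i in range(i0, i1):
        s += _trial_logpdf(rts[i], accs[i], v, a, t0, z, eps)
    return s


def wfpt_density(t, v: float, a: float, t0: float, z: float,
                 boundary: str = "upper", eps: float = DEFAULT_EPS):
    """First-passage density of the DDM at the named boundary.

    Parameters
    ----------
    t
        Observed time(s) in seconds (including non-decision time ``t0``);
        scalar or array.  Times at or below ``t0`` get density 0.
    v, a, t0, z
        Drift rate, boundary separation, non-decision time and start
        proportion.
    boundary
        ``"upper"`` (correct) or ``"lower"`` (error).
    eps
        Absolute series-truncation tolerance.

    Returns
    -------
    float or ndarray of densities (>= 0).
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    for name, val in (("v", v), ("a", a), ("t0", t0), ("z", z)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite parameter {name}={val}")
    if not (a > 0 and 0 < z < 1):
        raise ValueError(f"invalid parameters a={a}, z={z}")
    up = boundary == "upper"
    tarr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    out = np.empty_like(tarr)
    for i, ti in enumerate(tarr):
        out[i] = _wfpt_pdf(ti - t0, v, a, z, up, eps)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def absorption_probability(v: float, a: float, z: float) -> float:
    """Closed-form probability that the process absorbs at the upper boundary.

    For drift ``v``, boundary separation ``a`` and start proportion ``z``
    (diffusion coefficient 1) this is ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``,
    with the limit ``z`` as ``v -> 0``.
    """
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return z
    return float(np.expm1(-x * z) / np.expm1(-x))


def loglik(trials, params, eps: float = DEFAULT_EPS) -> float:
    """Accuracy-coded log-likelihood of a slice of trials under one parameter set.

    ``trials`` is anything with ``rt`` and ``accuracy`` columns/fields (a
    pandas DataFrame slice or a dict of arrays); ``params`` has attributes
    or keys ``v, a, t0, z``.  Correct trials are scored at the upper
    boundary, errors at the lower.  Trials with ``rt <= t0`` contribute the
    LOG_FLOOR penalty rather than ``-inf``.  An empty slice scores 0.
    """
    rts = np.asarray(trials["rt"], dtype=np.float64)
    accs = np.asarray(trials["accuracy"], dtype=np.int64)
    if rts.size == 0:
        return 0.0
    if not np.all(np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError("all trial RTs must be finite and positive")
    if hasattr(params, "v"):
        v, a, t0, z = params.v, params.a, params.t0, params.z
    else:
        v, a, t0, z = params["v"], params["a"], params["t0"], params["z"]
    return float(_slice_loglik(rts, accs, 0, rts.size, float(v), float(a),
                               float(t0), float(z), eps))
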