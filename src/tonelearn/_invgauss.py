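"""First-passage (inverse-Gaussian / Wald) density and survival primitives.

A unit-diffusion Wiener process started at 0 with drift ``mu > 0`` first
reaches the level ``b > 0`` at a random time with density

    f(t; mu, b) = b (2 pi t^3)^{-1/2} exp(-(b - mu t)^2 / (2 t)),

the inverse-Gaussian distribution with mean ``b/mu`` and shape ``b^2``.
These functions are the likelihood kernel of the race model, so they are
kept numerically careful (log forms, log-space guard on the exp(2*mu*b)
term of the CDF) and are mirrored by numba-compiled versions used inside
the MCMC inner loop when numba is importable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import log_ndtr, ndtr

_LOG_2PI = math.log(2.0 * math.pi)


def _validate(t, mu, b, allow_zero_t: bool = False):
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0.0) or np.any(mu <= 0.0):
        raise ValueError("mu and b must be strictly positive")
    if allow_zero_t:
        if np.any(t < 0.0):
            raise ValueError("t must be non-negative")
    elif np.any(t <= 0.0):
        raise ValueError("t must be strictly positive")
    return t, mu, b


def ig_logpdf(t, mu, b):
    """Log first-passage density log f(t; mu, b)."""
    t, mu, b = _validate(t, mu, b)
    return np.log(b) - 0.5 * (_LOG_2PI + 3.0 * np.log(t)) - (b - mu * t) ** 2 / (2.0 * t)


def ig_pdf(t, mu, b):
    """First-passage density f(t; mu, b) = b (2 pi t^3)^{-1/2} exp(-(b-mu t)^2/(2t))."""
    return np.exp(ig_logpdf(t, mu, b))


def ig_logsf(t, mu, b):
    """Log survival function of the first-passage time.

    S(t) = 1 - [Phi((mu t - b)/sqrt(t)) + e^{2 mu b} Phi(-(mu t + b)/sqrt(t))]
         = Phi((b - mu t)/sqrt(t)) - exp(2 mu b + log Phi(-(mu t + b)/sqrt(t))),

    evaluated as logPhi((b-mu t)/sqrt t) + log1p(-exp(ratio)) so the
    exp(2 mu b) factor never overflows.
    """
    t, mu, b = _validate(t, mu, b, allow_zero_t=True)
    t = np.where(t == 0.0, np.finfo(float).tiny, t)
    sqrt_t = np.sqrt(t)
    c1 = (b - mu * t) / sqrt_t
    c2 = -(mu * t + b) / sqrt_t
    log_a = log_ndtr(c1)
    log_b = 2.0 * mu * b + log_ndtr(c2)
    # ratio = second term / first term, always < 1 since S(t) > 0
    with np.errstate(over="ignore"):
        ratio = np.exp(np.minimum(log_b - log_a, 0.0))
    out = log_a + np.log1p(-np.minimum(ratio, 1.0 - 1e-16))
    return np.where(np.asarray(t) <= np.finfo(float).tiny, 0.0, out)


def ig_sf(t, mu, b):
    """Survival probability P(first passage > t); ig_sf(0) = 1."""
    return np.exp(ig_logsf(t, mu, b))


def ig_cdf(t, mu, b):
    """CDF Phi((mu t - b)/sqrt t) + e^{2 mu b} Phi(-(mu t + b)/sqrt t)."""
    t, mu, b = _validate(t, mu, b, allow_zero_t=True)
    tt = np.where(t == 0.0, np.finfo(float).tiny, t)
    sqrt_t = np.sqrt(tt)
    first = ndtr((mu * tt - b) / sqrt_t)
    second = np.exp(2.0 * mu * b + log_ndtr(-(mu * tt + b) / sqrt_t))
    return np.where(np.asarray(t) == 0.0, 0.0, np.clip(first + second, 0.0, 1.0))


# ---------------------------------------------------------------------------
# numba kernels for the sampler hot loop (optional; numpy fallback otherwise)
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised indirectly through the sampler
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _log_ndtr_scalar(x: float) -> float:
        if x > -1.0:
            return math.log1p(-0.5 * math.erfc(x / math.sqrt(2.0)))
        if x > -30.0:
            return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
        # asymptotic expansion for the far lower tail
        x2 = x * x
        return (-0.5 * x2 - 0.5 * _LOG_2PI - math.log(-x)
                + math.log1p(-1.0 / x2 + 3.0 / (x2 * x2)))

    @njit(cache=True, fastmath=False)
    def _contrib_kernel(t_adj, mu_v, b_v, is_resp, out):
        """Per-trial log contribution of one accumulator: log-pdf if it won, log-sf otherwise."""
        for k in range(t_adj.shape[0]):
            t = t_adj[k]
            if t <= 0.0:
                out[k] = -np.inf
                continue
            mu = mu_v[k]
            b = b_v[k]
            if is_resp[k]:
                out[k] = (math.log(b) - 0.5 * (_LOG_2PI + 3.0 * math.log(t))
                          - (b - mu * t) ** 2 / (2.0 * t))
            else:
                st = math.sqrt(t)
                log_a = _log_ndtr_scalar((b - mu * t) / st)
                log_b = 2.0 * mu * b + _log_ndtr_scalar(-(mu * t + b) / st)
                r = log_b - log_a
                if r > -1e-16:
                    r = -1e-16
                out[k] = log_a + math.log1p(-math.exp(r))
        return out

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _contrib_kernel(t_adj, mu_v, b_v, is_resp, out):
        bad = t_adj <= 0.0
        tt = np.where(bad, 1.0, t_adj)
        lp = (np.log(b_v) - 0.5 * (_LOG_2PI + 3.0 * np.log(tt))
              - (b_v - mu_v * tt) ** 2 / (2.0 * tt))
        sqrt_t = np.sqrt(tt)
        log_a = log_ndtr((b_v - mu_v * tt) / sqrt_t)
        log_b = 2.0 * mu_v * b_v + log_ndtr(-(mu_v * tt + b_v) / sqrt_t)
        ls = log_a + np.log1p(-np.exp(np.minimum(log_b - log_a, -1e-16)))
        out[:] = np.where(bad, -np.inf, np.where(is_resp, lp, ls))
        return out


def accumulator_contrib(t_adj, mu_v, b_v, is_resp):
    """Vector of per-trial log contributions of one accumulator to the race likelihood."""
    t_adj = np.ascontiguousarray(t_adj, dtype=np.float64)
    out = np.empty(t_adj.shape[0])
    _contrib_kernel(t_adj, np.ascontiguousarray(mu_v, dtype=np.float64),
                    np.ascontiguousarray(b_v, dtype=np.float64),
                    np.ascontiguousarray(is_resp, dtype=np.bool_), out)
    return out
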