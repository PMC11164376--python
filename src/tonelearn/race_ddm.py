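"""Multi-alternative inverse-Gaussian race model with longitudinal hierarchy.

Each categorization trial is modelled as a race between four independent
evidence accumulators, one per response option d.  On a trial with stimulus
category s, accumulator d is a unit-diffusion Wiener process with drift
``mu[d, s]`` and absorbing boundary ``b[d]`` (boundaries vary by response
only); the first accumulator to reach its boundary determines the choice,
and the response time is the crossing time plus a non-decision offset
``delta[s]``.  The joint density of (choice d, RT tau) is therefore

    f(tau - delta; mu_{d,s}, b_d) * prod_{d' != d} S(tau - delta; mu_{d',s}, b_{d'})

with f and S the inverse-Gaussian first-passage density and survival
function.

Drifts and boundaries carry a participant- and block-varying structure:
log-drift and log-boundary curves over the six training blocks are B-spline
expansions with population-level coefficients plus zero-mean Gaussian
participant deviations (shrinkage, inverse-gamma variance hyperpriors), and
participant x stimulus non-decision offsets have uniform priors bounded by
the smallest observed RT in the cell.  Sessions are fitted separately.

Inference is adaptive random-walk Metropolis-within-Gibbs on the log-scale
coefficients; participant-level blocks are updated in parallel across
participants (their full conditionals are independent given the population
level, so the compound kernel is a composition of valid MH kernels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

from ._invgauss import (
    accumulator_contrib,
    ig_cdf,
    ig_logpdf,
    ig_logsf,
    ig_pdf,
    ig_sf,
)
from .task_design import GENERALIZATION_BLOCK

__all__ = [
    "BasisSpec",
    "DDMParamSet",
    "PosteriorFit",
    "RaceDDM",
    "build_basis",
    "correct_drift_summary",
    "fit_session",
    "geweke_diag",
    "ig_pdf",
    "ig_logpdf",
    "ig_sf",
    "ig_logsf",
    "ig_cdf",
    "posterior_predictive_check",
    "race_loglik",
]

logger = logging.getLogger(__name__)

N_CAT = 4


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSpec:
    """B-spline basis over the block axis 1..n_blocks.

    The default is a cubic basis with interior knots at every interior block
    (2..5 on the six-block axis), giving 8 basis functions: flexible enough
    to interpolate any block profile while the smoothing prior shrinks
    wiggliness.
    """

    degree: int = 3
    interior_knots: tuple = (2.0, 3.0, 4.0, 5.0)
    n_blocks: int = 6

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1


def _knots(spec: BasisSpec) -> np.ndarray:
    """Full clamped knot vector of the basis."""
    lo, hi = 1.0, float(spec.n_blocks)
    inner = [k for k in spec.interior_knots if lo < k < hi]
    if len(inner) != len(spec.interior_knots):
        raise ValueError("interior knots must lie strictly inside (1, n_blocks)")
    return np.r_[[lo] * (spec.degree + 1), inner, [hi] * (spec.degree + 1)]


def build_basis(spec: BasisSpec | None = None) -> np.ndarray:
    """Dense B-spline design matrix, one row per block (partition of unity)."""
    spec = spec or BasisSpec()
    if spec.degree < 0 or spec.n_blocks < 1:
        raise ValueError("invalid basis spec")
    lo, hi = 1.0, float(spec.n_blocks)
    t = _knots(spec)
    x = np.arange(1, spec.n_blocks + 1, dtype=float)
    # clip the right endpoint into the final half-open interval
    x_eval = np.minimum(x, hi - 1e-9) if spec.degree >= 0 else x
    design = BSpline.design_matrix(x_eval, t, spec.degree).toarray()
    if design.shape[1] != len(t) - spec.degree - 1:
        raise ValueError("basis construction failed")  # pragma: no cover
    return design


def _second_diff_penalty(k: int, ridge: float = 1e-3) -> np.ndarray:
    """Second-difference roughness penalty with a small ridge (proper prior)."""
    if k < 3:
        return np.eye(k)
    d2 = np.zeros((k - 2, k))
    for j in range(k - 2):
        d2[j, j : j + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2 + ridge * np.eye(k)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def race_loglik(trial, mu: np.ndarray, b: np.ndarray, delta: float) -> float:
    """Log joint density of one trial's (choice, RT) under the race model.

    Parameters
    ----------
    trial
        Mapping with keys ``rt``, ``response`` (1-4) and ``tone_category``
        (1-4); only ``rt`` and ``response`` enter (``mu`` is already the
        drift column for the trial's stimulus category).
    mu, b
        Length-4 drift and boundary vectors for the trial's stimulus and
        block.
    delta
        Non-decision offset (seconds) for the participant x stimulus cell.

    RTs at or below ``delta`` yield ``-inf`` (never an exception), so the
    sampler can treat them as zero-probability proposals.
    """
    tau = float(trial["rt"]) - float(delta)
    if tau <= 0.0:
        return -np.inf
    d = int(trial["response"]) - 1
    total = float(ig_logpdf(tau, mu[d], b[d]))
    for dd in range(len(mu)):
        if dd != d:
            total += float(ig_logsf(tau, mu[dd], b[dd]))
    return total


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class DDMParamSet:
    """Point values of all race-model parameters for one session.

    ``mu[i, d, s, block]`` drifts, ``b[i, d, block]`` boundaries,
    ``delta[i, s]`` offsets, plus population-level curves
    ``mu_pop[d, s, block]`` and ``b_pop[d, block]``.
    """

    mu: np.ndarray
    b: np.ndarray
    delta: np.ndarray
    mu_pop: np.ndarray
    b_pop: np.ndarray


@dataclass
class PosteriorFit:
    """Retained draws, posterior summaries and diagnostics for one session."""

    draws: dict
    posterior_mean: DDMParamSet
    ci95: dict
    diagnostics: dict
    mcmc_config: dict
    participants: list
    session: object = None
    basis: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws["mu_pop"].shape[0]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class RaceDDM(BaseEstimator):
    """Hierarchical Bayesian race drift-diffusion model for one session.

    Parameters
    ----------
    n_iter, burn_in, thin
        MCMC schedule; the defaults (6000, 2000, 5) retain 800 draws.
    degree, interior_knots
        B-spline basis for the block trajectories of log drift/boundary.
    smooth_tau
        Precision of the second-difference smoothing prior on population
        coefficients.
    dev_a0, dev_b0
        Inverse-gamma hyperprior on the participant-deviation variances.
    target_accept
        Adaptive random-walk target acceptance rate (adaptation runs during
        burn-in only).
    delta_upper_frac
        Upper bound of each delta's uniform prior as a fraction of the
        smallest observed RT in its participant x stimulus cell.
    include_generalization
        If True, feedback-free generalization trials enter the likelihood
        with the final training block's parameters; default excludes them.
    monitor_frac
        Fraction of participant-level drift chains monitored by the Geweke
        diagnostic (population chains are always monitored).

    Attributes
    ----------
    fit_ : PosteriorFit
    posterior_mean_ : DDMParamSet
    participants_ : list of participant ids in index order
    acceptance_ : dict of mean acceptance rates per update family
    """

    def __init__(
        self,
        n_iter: int = 6000,
        burn_in: int = 2000,
        thin: int = 5,
        degree: int = 3,
        interior_knots: tuple = (2.0, 3.0, 4.0, 5.0),
        smooth_tau: float = 4.0,
        dev_a0: float = 2.0,
        dev_b0: float = 0.05,
        sig2_floor: float = 0.1,
        target_accept: float = 0.3,
        delta_upper_frac: float = 0.995,
        include_generalization: bool = False,
        monitor_frac: float = 0.1,
        n_blocks: int = 6,
        random_state=None,
        verbose: bool = False,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.degree = degree
        self.interior_knots = interior_knots
        self.smooth_tau = smooth_tau
        self.dev_a0 = dev_a0
        self.dev_b0 = dev_b0
        self.sig2_floor = sig2_floor
        self.target_accept = target_accept
        self.delta_upper_frac = delta_upper_frac
        self.include_generalization = include_generalization
        self.monitor_frac = monitor_frac
        self.n_blocks = n_blocks
        self.random_state = random_state
        self.verbose = verbose

    # -- data preparation ---------------------------------------------------

    def _encode(self, trials: pd.DataFrame):
        required = {"participant_id", "block", "tone_category", "response", "rt"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trials table lacks columns: {sorted(missing)}")
        tr = trials.copy()
        tr["block"] = tr["block"].astype(str)
        if self.include_generalization:
            tr.loc[tr["block"] == GENERALIZATION_BLOCK, "block"] = str(self.n_blocks)
        else:
            tr = tr[tr["block"] != GENERALIZATION_BLOCK]
        tr = tr[tr["block"].isin([str(k) for k in range(1, self.n_blocks + 1)])]
        if len(tr) == 0:
            raise ValueError("no training-block trials to fit")
        pids = sorted(tr["participant_id"].unique())
        pindex = {p: i for i, p in enumerate(pids)}
        i_arr = tr["participant_id"].map(pindex).to_numpy(dtype=np.int64)
        s_arr = tr["tone_category"].to_numpy(dtype=np.int64) - 1
        d_arr = tr["response"].to_numpy(dtype=np.int64) - 1
        bl_arr = tr["block"].astype(int).to_numpy(dtype=np.int64) - 1
        rt = tr["rt"].to_numpy(dtype=np.float64)
        if np.any(rt <= 0):
            raise ValueError("all RTs must be positive")
        return pids, i_arr, s_arr, d_arr, bl_arr, rt

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Run the MCMC on one session's trimmed trial table."""
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        rng = np.random.default_rng(self.random_state)
        pids, i_arr, s_arr, d_arr, bl_arr, rt = self._encode(X)
        n = len(pids)
        N = len(rt)
        spec = BasisSpec(self.degree, tuple(self.interior_knots), self.n_blocks)
        B = build_basis(spec)  # (n_blocks, K)
        K = B.shape[1]
        P = _second_diff_penalty(K)
        # Participant deviations use a reduced level + slope basis around the
        # population spline: individual differences in these trajectories are
        # dominated by overall level and learning-slope shifts, and the
        # two-coefficient parameterization keeps them identified from the
        # ~60 trials a participant contributes per stimulus cell.
        z_block = (np.arange(1, self.n_blocks + 1) - (1 + self.n_blocks) / 2.0) / (
            (self.n_blocks - 1) / 2.0
        )
        Bd = np.column_stack([np.ones(self.n_blocks), z_block])  # (n_blocks, 2)
        Kd = Bd.shape[1]

        # per-stimulus trial index sets
        idx_s = [np.where(s_arr == s0)[0] for s0 in range(N_CAT)]
        sub_i = [i_arr[ix] for ix in idx_s]
        sub_bl = [bl_arr[ix] for ix in idx_s]
        sub_d = [d_arr[ix] for ix in idx_s]
        sub_rt = [rt[ix] for ix in idx_s]

        # delta prior upper bounds: fraction of min observed RT per (i, s)
        min_rt = np.full((n, N_CAT), np.inf)
        np.minimum.at(min_rt, (i_arr, s_arr), rt)
        empty_cells = int(np.sum(~np.isfinite(min_rt)))
        if empty_cells:
            warnings.warn(
                f"{empty_cells} participant x stimulus cells have no trials; "
                "their parameters follow prior-only updates",
                stacklevel=2,
            )
            min_rt[~np.isfinite(min_rt)] = float(np.median(rt))
        delta_hi = self.delta_upper_frac * min_rt

        # ---- state: moment-based initialization ----
        # Random-walk chains started at a flat common value take thousands of
        # iterations to spread the participant deviations, so each component
        # starts at a crude method-of-moments estimate: boundaries from the
        # inverse-Gaussian mean/variance relation of the winning passage
        # times (lambda = m^3/v, b = sqrt(lambda)), the overall drift level
        # from b / mean RT, and the correct-to-incorrect drift ratio from
        # cell accuracy.  Disengaged participants (fast but at chance) are
        # thereby initialized with low boundaries and flat drifts rather
        # than fast learner-like ones.
        delta = 0.5 * min_rt
        t_adj0 = rt - delta[i_arr, s_arr]
        greville = np.array(
            [np.mean(_knots(spec)[k + 1 : k + spec.degree + 1]) for k in range(K)]
        ) if spec.degree > 0 else np.arange(1, K + 1, dtype=float)

        # per-participant boundary from pooled winner-RT moments
        m_i = np.bincount(i_arr, weights=t_adj0, minlength=n) / np.maximum(
            np.bincount(i_arr, minlength=n), 1
        )
        v_i = np.bincount(i_arr, weights=(t_adj0 - m_i[i_arr]) ** 2, minlength=n) / np.maximum(
            np.bincount(i_arr, minlength=n) - 1, 1
        )
        b_hat = np.clip(np.sqrt(m_i**3 / np.maximum(v_i, 1e-6)), 0.5, 3.0)

        def cell_stat(mask, values):
            num = np.zeros((n, N_CAT))
            den = np.zeros((n, N_CAT))
            np.add.at(num, (i_arr[mask], s_arr[mask]), values[mask])
            np.add.at(den, (i_arr[mask], s_arr[mask]), 1.0)
            return num, den

        all_mask = np.ones(len(rt), dtype=bool)
        rt_sum, n_cell = cell_stat(all_mask, t_adj0)
        corr_sum, _ = cell_stat(all_mask, (d_arr == s_arr).astype(float))
        m_cell = np.where(n_cell > 0, rt_sum / np.maximum(n_cell, 1.0), m_i[:, None])
        p_cell = np.clip(
            np.where(n_cell > 0, corr_sum / np.maximum(n_cell, 1.0), 0.25), 0.26, 0.95
        )
        ratio = np.clip(np.sqrt(3.0 * p_cell / (1.0 - p_cell)), 1.0, 4.0)
        mu_base = np.clip(0.7 * b_hat[:, None] / m_cell, 0.15, 5.0)
        log_mu_c = np.log(np.clip(mu_base * ratio, 0.2, 6.0))  # (n, s)
        log_mu_w = np.log(mu_base)

        # population trend for correct cells from early/late block halves
        half = bl_arr >= self.n_blocks // 2
        beta_pop = np.empty((N_CAT, N_CAT, K))
        for s0 in range(N_CAT):
            levels = []
            for hmask in (~half, half):
                m = (s_arr == s0) & hmask
                if m.any():
                    p_h = np.clip(np.mean(d_arr[m] == s0), 0.26, 0.95)
                    r_h = np.clip(np.sqrt(3.0 * p_h / (1.0 - p_h)), 1.0, 4.0)
                    mu_h = np.clip(0.7 * np.mean(b_hat) / np.mean(t_adj0[m]), 0.15, 5.0)
                    levels.append(np.log(np.clip(mu_h * r_h, 0.2, 6.0)))
                else:
                    levels.append(float(np.mean(log_mu_c[:, s0])))
            centers = (
                (1.0 + self.n_blocks // 2) / 2.0,
                (self.n_blocks // 2 + 1 + self.n_blocks) / 2.0,
            )
            slope = (levels[1] - levels[0]) / max(centers[1] - centers[0], 1.0)
            curve = levels[0] + slope * (greville - centers[0])
            for d0 in range(N_CAT):
                beta_pop[d0, s0] = curve if d0 == s0 else float(np.mean(log_mu_w[:, s0]))
        gamma_pop = np.repeat(np.log(b_hat).mean(), K)[None, :].repeat(N_CAT, axis=0)
        beta_dev = np.zeros((n, N_CAT, N_CAT, Kd))
        for s0 in range(N_CAT):
            for d0 in range(N_CAT):
                lvl = log_mu_c[:, s0] if d0 == s0 else log_mu_w[:, s0]
                beta_dev[:, d0, s0, 0] = lvl - lvl.mean()
        gamma_dev = np.zeros((n, N_CAT, Kd))
        gamma_dev[:, :, 0] = (np.log(b_hat) - np.log(b_hat).mean())[:, None]
        # Deviation variances start generous and are held fixed throughout
        # burn-in: starting the conjugate updates with all deviations at
        # zero would collapse the shrinkage variance at once and trap the
        # sampler in the neck of the hierarchical funnel, so the Gibbs step
        # begins only once the deviations have equilibrated.  One variance
        # per (d, s) drift cell / per response boundary, since
        # correct-response cells carry far more participant heterogeneity
        # than incorrect ones.
        sig2_beta = np.full((N_CAT, N_CAT), 0.25)
        sig2_gamma = np.full(N_CAT, 0.25)
        hyper_warmup = self.burn_in // 2

        def invgamma_lp(s2):
            return -(self.dev_a0 + 1.0) * np.log(s2) - self.dev_b0 / s2

        mu = np.exp(
            np.einsum("dsk,bk->dsb", beta_pop, B)[None, ...]
            + np.einsum("idsk,bk->idsb", beta_dev, Bd)
        )  # (n, d, s, block)
        bnd = np.exp(
            np.einsum("dk,bk->db", gamma_pop, B)[None, ...]
            + np.einsum("idk,bk->idb", gamma_dev, Bd)
        )  # (n, d, block)

        def cell_sums_for(s0, d0, mu_slice, b_slice, delta_col):
            """Per-participant likelihood contribution of accumulator d0 on stimulus-s0 trials."""
            ii, bb = sub_i[s0], sub_bl[s0]
            t_adj = sub_rt[s0] - delta_col[ii]
            contrib = accumulator_contrib(
                t_adj, mu_slice[ii, bb], b_slice[ii, bb], sub_d[s0] == d0
            )
            return np.bincount(ii, weights=contrib, minlength=n)

        # S[i, s, d] = summed log contribution of accumulator d on cell (i, s)
        S = np.zeros((n, N_CAT, N_CAT))
        for s0 in range(N_CAT):
            for d0 in range(N_CAT):
                S[:, s0, d0] = cell_sums_for(s0, d0, mu[:, d0, s0, :], bnd[:, d0, :], delta[:, s0])

        # adaptive scales
        sc_pop_mu = np.full((N_CAT, N_CAT), 0.04)
        sc_pop_b = np.full(N_CAT, 0.02)
        sc_dev_mu = np.full((n, N_CAT, N_CAT), 0.12)
        sc_dev_b = np.full((n, N_CAT), 0.08)
        sc_delta = 0.05 * min_rt
        adapt_step = 0.08
        acc_counts = {"pop_mu": [0, 0], "pop_b": [0, 0], "dev_mu": [0, 0],
                      "dev_b": [0, 0], "delta": [0, 0]}

        def smooth_lp(coef):
            return -0.5 * self.smooth_tau * float(coef @ P @ coef)

        n_keep = (self.n_iter - self.burn_in) // self.thin
        draws_mu = np.empty((n_keep, n, N_CAT, N_CAT, self.n_blocks), dtype=np.float32)
        draws_b = np.empty((n_keep, n, N_CAT, self.n_blocks), dtype=np.float32)
        draws_delta = np.empty((n_keep, n, N_CAT), dtype=np.float32)
        draws_mu_pop = np.empty((n_keep, N_CAT, N_CAT, self.n_blocks), dtype=np.float32)
        draws_b_pop = np.empty((n_keep, N_CAT, self.n_blocks), dtype=np.float32)
        draws_sig2 = np.empty((n_keep, N_CAT * N_CAT + N_CAT), dtype=np.float32)
        loglik_trace = np.empty(self.n_iter)
        keep = 0

        for it in range(self.n_iter):
            adapting = it < self.burn_in

            # ---- population drift curves ----
            for d0 in range(N_CAT):
                for s0 in range(N_CAT):
                    prop = beta_pop[d0, s0] + sc_pop_mu[d0, s0] * rng.standard_normal(K)
                    lm = (prop @ B.T)[None, :] + beta_dev[:, d0, s0, :] @ Bd.T
                    mu_new = np.exp(lm)
                    new_sums = cell_sums_for(s0, d0, mu_new, bnd[:, d0, :], delta[:, s0])
                    dll = new_sums.sum() - S[:, s0, d0].sum()
                    dlp = smooth_lp(prop) - smooth_lp(beta_pop[d0, s0])
                    acc = np.log(rng.random()) < dll + dlp
                    acc_counts["pop_mu"][0] += int(acc)
                    acc_counts["pop_mu"][1] += 1
                    if acc:
                        beta_pop[d0, s0] = prop
                        mu[:, d0, s0, :] = mu_new
                        S[:, s0, d0] = new_sums
                    if adapting:
                        sc_pop_mu[d0, s0] *= np.exp(adapt_step * ((1.0 if acc else 0.0) - self.target_accept))

            # ---- population boundary curves ----
            t_adj_all = rt - delta[i_arr, s_arr]
            for d0 in range(N_CAT):
                prop = gamma_pop[d0] + sc_pop_b[d0] * rng.standard_normal(K)
                b_new = np.exp((prop @ B.T)[None, :] + gamma_dev[:, d0, :] @ Bd.T)
                contrib = accumulator_contrib(
                    t_adj_all, mu[i_arr, d0, s_arr, bl_arr], b_new[i_arr, bl_arr], d_arr == d0
                )
                new_cells = np.bincount(i_arr * N_CAT + s_arr, weights=contrib,
                                        minlength=n * N_CAT).reshape(n, N_CAT)
                dll = new_cells.sum() - S[:, :, d0].sum()
                dlp = smooth_lp(prop) - smooth_lp(gamma_pop[d0])
                acc = np.log(rng.random()) < dll + dlp
                acc_counts["pop_b"][0] += int(acc)
                acc_counts["pop_b"][1] += 1
                if acc:
                    gamma_pop[d0] = prop
                    bnd[:, d0, :] = b_new
                    S[:, :, d0] = new_cells
                if adapting:
                    sc_pop_b[d0] *= np.exp(adapt_step * ((1.0 if acc else 0.0) - self.target_accept))

            # ---- participant drift deviations (parallel across participants) ----
            # two move types per cell: a full K-vector random walk (shape)
            # and a constant shift of the whole curve (level), which mixes
            # the dominant participant-offset direction much faster
            for d0 in range(N_CAT):
                for s0 in range(N_CAT):
                    pop_curve = beta_pop[d0, s0] @ B.T
                    for shift_move in (False, True):
                        eps = np.zeros((n, Kd))
                        if shift_move:
                            eps[:, 0] = 2.0 * sc_dev_mu[:, d0, s0] * rng.standard_normal(n)
                        else:
                            eps = sc_dev_mu[:, d0, s0, None] * rng.standard_normal((n, Kd))
                        prop = beta_dev[:, d0, s0, :] + eps
                        mu_new = np.exp(pop_curve[None, :] + prop @ Bd.T)
                        new_sums = cell_sums_for(s0, d0, mu_new, bnd[:, d0, :], delta[:, s0])
                        dll = new_sums - S[:, s0, d0]
                        dlp = 0.5 * (
                            np.sum(beta_dev[:, d0, s0, :] ** 2, axis=1) - np.sum(prop**2, axis=1)
                        ) / sig2_beta[d0, s0]
                        acc = np.log(rng.random(n)) < dll + dlp
                        acc_counts["dev_mu"][0] += int(acc.sum())
                        acc_counts["dev_mu"][1] += n
                        beta_dev[acc, d0, s0, :] = prop[acc]
                        mu[acc, d0, s0, :] = mu_new[acc]
                        S[acc, s0, d0] = new_sums[acc]
                        if adapting and not shift_move:
                            sc_dev_mu[:, d0, s0] *= np.exp(adapt_step * (acc - self.target_accept))

            # ---- participant boundary deviations ----
            for d0 in range(N_CAT):
                eps = sc_dev_b[:, d0, None] * rng.standard_normal((n, Kd))
                prop = gamma_dev[:, d0, :] + eps
                b_new = np.exp((gamma_pop[d0] @ B.T)[None, :] + prop @ Bd.T)
                contrib = accumulator_contrib(
                    t_adj_all, mu[i_arr, d0, s_arr, bl_arr], b_new[i_arr, bl_arr], d_arr == d0
                )
                new_cells = np.bincount(i_arr * N_CAT + s_arr, weights=contrib,
                                        minlength=n * N_CAT).reshape(n, N_CAT)
                dll = new_cells.sum(axis=1) - S[:, :, d0].sum(axis=1)
                dlp = 0.5 * (
                    np.sum(gamma_dev[:, d0, :] ** 2, axis=1) - np.sum(prop**2, axis=1)
                ) / sig2_gamma[d0]
                acc = np.log(rng.random(n)) < dll + dlp
                acc_counts["dev_b"][0] += int(acc.sum())
                acc_counts["dev_b"][1] += n
                gamma_dev[acc, d0, :] = prop[acc]
                bnd[acc, d0, :] = b_new[acc]
                S[acc, :, d0] = new_cells[acc]
                if adapting:
                    sc_dev_b[:, d0] *= np.exp(adapt_step * (acc - self.target_accept))

            # ---- non-decision offsets (uniform prior, reflective random walk) ----
            for s0 in range(N_CAT):
                lo = 1e-4
                hi = delta_hi[:, s0]
                prop = delta[:, s0] + sc_delta[:, s0] * rng.standard_normal(n)
                prop = np.where(prop < lo, 2 * lo - prop, prop)
                prop = np.where(prop > hi, 2 * hi - prop, prop)
                ok = (prop > 0) & (prop < hi)
                new_cells = np.zeros((n, N_CAT))
                for d0 in range(N_CAT):
                    new_cells[:, d0] = cell_sums_for(s0, d0, mu[:, d0, s0, :], bnd[:, d0, :], prop)
                dll = new_cells.sum(axis=1) - S[:, s0, :].sum(axis=1)
                acc = ok & (np.log(rng.random(n)) < dll)
                acc_counts["delta"][0] += int(acc.sum())
                acc_counts["delta"][1] += n
                delta[acc, s0] = prop[acc]
                S[acc, s0, :] = new_cells[acc]
                if acc.any():
                    t_adj_all = rt - delta[i_arr, s_arr]
                if adapting:
                    sc_delta[:, s0] *= np.exp(adapt_step * (acc - self.target_accept))

            # ---- deviation variances (conjugate inverse-gamma Gibbs) ----
            if it >= hyper_warmup:
                # inverse-gamma Gibbs, truncated below at sig2_floor: the
                # hyperprior is IG restricted to [floor, inf), which keeps a
                # minimum amount of participant-level flexibility and stops
                # the shrinkage variance from degenerating in the funnel
                ss_beta = np.sum(beta_dev**2, axis=(0, 3))  # (d, s)
                sig2_beta = np.maximum(
                    (self.dev_b0 + 0.5 * ss_beta) / rng.gamma(
                        self.dev_a0 + 0.5 * n * Kd, size=(N_CAT, N_CAT)
                    ),
                    self.sig2_floor,
                )
                ss_gamma = np.sum(gamma_dev**2, axis=(0, 2))  # (d,)
                sig2_gamma = np.maximum(
                    (self.dev_b0 + 0.5 * ss_gamma) / rng.gamma(
                        self.dev_a0 + 0.5 * n * Kd, size=N_CAT
                    ),
                    self.sig2_floor,
                )

                # ---- interweaved scale moves along the funnel axis ----
                # rescale a cell's deviations and its variance jointly:
                # (dev, s2) -> (c dev, c^2 s2); the Gaussian prior ratio
                # cancels the dev Jacobian, leaving likelihood x IG x c^2
                for d0 in range(N_CAT):
                    for s0 in range(N_CAT):
                        z = 0.25 * rng.standard_normal()
                        c = np.exp(z)
                        prop = c * beta_dev[:, d0, s0, :]
                        s2_new = c * c * sig2_beta[d0, s0]
                        if s2_new < self.sig2_floor:  # truncated hyperprior support
                            continue
                        mu_new = np.exp((beta_pop[d0, s0] @ B.T)[None, :] + prop @ Bd.T)
                        new_sums = cell_sums_for(s0, d0, mu_new, bnd[:, d0, :], delta[:, s0])
                        dll = new_sums.sum() - S[:, s0, d0].sum()
                        dlp = invgamma_lp(s2_new) - invgamma_lp(sig2_beta[d0, s0])
                        if np.log(rng.random()) < dll + dlp + 2.0 * z:
                            beta_dev[:, d0, s0, :] = prop
                            sig2_beta[d0, s0] = s2_new
                            mu[:, d0, s0, :] = mu_new
                            S[:, s0, d0] = new_sums
                t_adj_all = rt - delta[i_arr, s_arr]
                for d0 in range(N_CAT):
                    z = 0.25 * rng.standard_normal()
                    c = np.exp(z)
                    prop = c * gamma_dev[:, d0, :]
                    s2_new = c * c * sig2_gamma[d0]
                    if s2_new < self.sig2_floor:
                        continue
                    b_new = np.exp((gamma_pop[d0] @ B.T)[None, :] + prop @ Bd.T)
                    contrib = accumulator_contrib(
                        t_adj_all, mu[i_arr, d0, s_arr, bl_arr], b_new[i_arr, bl_arr],
                        d_arr == d0,
                    )
                    new_cells = np.bincount(i_arr * N_CAT + s_arr, weights=contrib,
                                            minlength=n * N_CAT).reshape(n, N_CAT)
                    dll = new_cells.sum() - S[:, :, d0].sum()
                    dlp = invgamma_lp(s2_new) - invgamma_lp(sig2_gamma[d0])
                    if np.log(rng.random()) < dll + dlp + 2.0 * z:
                        gamma_dev[:, d0, :] = prop
                        sig2_gamma[d0] = s2_new
                        bnd[:, d0, :] = b_new
                        S[:, :, d0] = new_cells

            loglik_trace[it] = float(S.sum())
            if not adapting and (it - self.burn_in) % self.thin == self.thin - 1 and keep < n_keep:
                draws_mu[keep] = mu
                draws_b[keep] = bnd
                draws_delta[keep] = delta
                draws_mu_pop[keep] = np.exp(np.einsum("dsk,bk->dsb", beta_pop, B))
                draws_b_pop[keep] = np.exp(np.einsum("dk,bk->db", gamma_pop, B))
                draws_sig2[keep] = np.r_[sig2_beta.ravel(), sig2_gamma]
                keep += 1
            if self.verbose and (it + 1) % max(1, self.n_iter // 10) == 0:
                logger.info("iter %d/%d loglik %.1f", it + 1, self.n_iter, loglik_trace[it])

        rates = {k: (c[0] / c[1] if c[1] else np.nan) for k, c in acc_counts.items()}
        if any(not 0.1 <= r <= 0.6 for r in rates.values() if np.isfinite(r)):
            warnings.warn(f"proposal adaptation ended outside the target band: {rates}",
                          stacklevel=2)

        draws = {
            "mu": draws_mu[:keep],
            "b": draws_b[:keep],
            "delta": draws_delta[:keep],
            "mu_pop": draws_mu_pop[:keep],
            "b_pop": draws_b_pop[:keep],
            "sig2_dev": draws_sig2[:keep],
            "loglik": loglik_trace,
        }
        post_mean = DDMParamSet(
            mu=draws_mu[:keep].mean(axis=0).astype(float),
            b=draws_b[:keep].mean(axis=0).astype(float),
            delta=draws_delta[:keep].mean(axis=0).astype(float),
            mu_pop=draws_mu_pop[:keep].mean(axis=0).astype(float),
            b_pop=draws_b_pop[:keep].mean(axis=0).astype(float),
        )
        ci95 = {
            name: np.percentile(draws[name], [2.5, 97.5], axis=0).astype(float)
            for name in ("mu", "b", "delta", "mu_pop", "b_pop")
        }
        diagnostics = self._diagnostics(draws, rates, empty_cells, rng)
        session = X["session"].iloc[0] if "session" in X.columns and X["session"].nunique() == 1 else None
        self.participants_ = pids
        self.basis_ = B
        self.posterior_mean_ = post_mean
        self.ci95_ = ci95
        self.acceptance_ = rates
        self.fit_ = PosteriorFit(
            draws=draws,
            posterior_mean=post_mean,
            ci95=ci95,
            diagnostics=diagnostics,
            mcmc_config={
                "n_iter": self.n_iter, "burn_in": self.burn_in, "thin": self.thin,
                "n_retained": keep, "basis_size": K,
            },
            participants=pids,
            session=session,
            basis=B,
        )
        return self

    def _diagnostics(self, draws, rates, empty_cells, rng) -> dict:
        """Geweke z-scores on population chains plus a participant-level subsample."""
        R = draws["mu_pop"].shape[0]
        chains = [draws["mu_pop"].reshape(R, -1), draws["b_pop"].reshape(R, -1)]
        mu_flat = draws["mu"].reshape(R, -1)
        n_monitor = max(1, int(self.monitor_frac * mu_flat.shape[1] / N_CAT))
        cols = rng.choice(mu_flat.shape[1], size=min(n_monitor, mu_flat.shape[1]), replace=False)
        chains.append(mu_flat[:, cols])
        stacked = np.concatenate(chains, axis=1)
        if R >= 100:
            z = np.array([geweke_diag(stacked[:, j]) for j in range(stacked.shape[1])])
            geweke = {
                "z": z,
                "frac_pass": float(np.mean(np.abs(z) < 2.0)),
                "n_chains": int(stacked.shape[1]),
            }
        else:
            logger.warning("retained chain too short for the Geweke diagnostic (%d draws)", R)
            geweke = {"z": None, "frac_pass": None, "n_chains": int(stacked.shape[1])}
        return {"geweke": geweke, "acceptance": rates, "n_empty_cells": empty_cells}


def fit_session(trials: pd.DataFrame, model_config: dict | None = None, rng_seed: int = 0) -> PosteriorFit:
    """Functional wrapper: fit one session's trials and return the PosteriorFit."""
    cfg = dict(model_config or {})
    cfg.setdefault("random_state", rng_seed)
    return RaceDDM(**cfg).fit(trials).fit_


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def correct_drift_summary(fit: PosteriorFit) -> pd.DataFrame:
    """Per participant x block summaries of the correct-accumulator drifts.

    ``drift`` is the plain average over the four accumulators with d = s of
    the posterior-mean drifts (learning is carried by these), and
    ``boundary`` the average posterior-mean boundary over the four responses.
    """
    pm = fit.posterior_mean
    n, _, _, n_blocks = pm.mu.shape
    diag = np.stack([pm.mu[:, s, s, :] for s in range(N_CAT)], axis=1)  # (n, 4, blocks)
    drift = diag.mean(axis=1)
    boundary = pm.b.mean(axis=1)
    rows = []
    for i, pid in enumerate(fit.participants):
        for bl in range(n_blocks):
            rows.append(
                {
                    "participant_id": pid,
                    "session": fit.session,
                    "block": bl + 1,
                    "drift": float(drift[i, bl]),
                    "boundary": float(boundary[i, bl]),
                }
            )
    return pd.DataFrame(rows)


def _spectral_var_at_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed autocovariance sum."""
    n = len(x)
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    if gamma0 == 0.0:
        return 0.0
    m = max(1, int(np.sqrt(n)))
    s = gamma0
    for k in range(1, m + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (m + 1.0)) * gk
    return max(s, 0.0)


def geweke_diag(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke stationarity z-score comparing early and late chain segments.

    z = (mean of first 10% - mean of last 50%) / sqrt(sum of spectral-density
    variance estimates).  |z| < 2 is conventionally a pass; a constant chain
    returns 0 by convention.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    if np.ptp(x) == 0.0:
        return 0.0
    a = x[: int(first * len(x))]
    b = x[-int(last * len(x)):]
    va = _spectral_var_at_zero(a) / len(a)
    vb = _spectral_var_at_zero(b) / len(b)
    if va + vb == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def posterior_predictive_check(
    fit: PosteriorFit,
    trials: pd.DataFrame,
    n_rep: int = 200,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate datasets from posterior draws and check block statistics.

    For each replicate a retained draw is selected at random and every
    observed trial is re-simulated from its (participant, stimulus, block)
    parameters.  Per-block accuracy and RT quantiles (0.1, 0.5, 0.9) of the
    observed data are compared with the replicate 95% intervals; the returned
    table has one row per (block, statistic) with a ``covered`` flag.
    """
    rng = np.random.default_rng(rng_seed)
    pindex = {p: i for i, p in enumerate(fit.participants)}
    tr = trials[trials["block"].astype(str) != GENERALIZATION_BLOCK]
    tr = tr[tr["participant_id"].isin(pindex)]
    i_arr = tr["participant_id"].map(pindex).to_numpy(dtype=int)
    s_arr = tr["tone_category"].to_numpy(dtype=int) - 1
    bl_arr = tr["block"].astype(int).to_numpy(dtype=int) - 1
    rt_obs = tr["rt"].to_numpy(dtype=float)
    corr_obs = tr["correct"].to_numpy(dtype=bool)

    blocks = np.unique(bl_arr)
    qs = (0.1, 0.5, 0.9)

    def block_stats(rt_v, corr_v):
        out = {}
        for bl in blocks:
            m = bl_arr == bl
            out[(bl + 1, "accuracy")] = float(np.mean(corr_v[m]))
            for q in qs:
                out[(bl + 1, f"rt_q{int(q * 100)}")] = float(np.quantile(rt_v[m], q))
        return out

    obs = block_stats(rt_obs, corr_obs)
    R = fit.n_draws
    rep_stats = {k: np.empty(n_rep) for k in obs}
    for r in range(n_rep):
        j = int(rng.integers(R))
        mu = fit.draws["mu"][j][i_arr, :, s_arr, bl_arr].astype(float)  # (N, 4)
        bb = fit.draws["b"][j][i_arr, :, bl_arr].astype(float)
        dd = fit.draws["delta"][j][i_arr, s_arr].astype(float)
        times = rng.wald(bb / mu, bb * bb)
        resp = np.argmin(times, axis=1)
        rt_sim = dd + times[np.arange(len(resp)), resp]
        corr_sim = resp == s_arr
        st = block_stats(rt_sim, corr_sim)
        for k in obs:
            rep_stats[k][r] = st[k]

    rows = []
    for (bl, stat), val in obs.items():
        lo, hi = np.percentile(rep_stats[(bl, stat)], [2.5, 97.5])
        rows.append(
            {
                "block": bl,
                "statistic": stat,
                "observed": val,
                "rep_lo": float(lo),
                "rep_hi": float(hi),
                "covered": bool(lo <= val <= hi),
            }
        )
    return pd.DataFrame(rows)
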