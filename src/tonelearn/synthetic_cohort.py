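"""Synthetic participants, OSPAN records, and trial-level choice/RT data.

The generator emulates the design of a three-session Mandarin tone learning
study: each participant carries a latent working-memory capacity on the OSPAN
scale (0-75), a learner/non-learner flag, block-resolution drift and boundary
trajectories for the four-accumulator inverse-Gaussian race, and per-category
non-decision offsets.  Learners' correct-accumulator log drifts rise over
blocks and sessions with a slope that increases with working memory and drop
at the start of each delayed session (forgetting); non-learners are modelled
as disengaged: flat low drifts and low boundaries, independent of working
memory.

All sampling is driven by a single seed through ``numpy.random.SeedSequence``
spawning, so a cohort and its full trial table are byte-reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task_design import (
    GENERALIZATION_BLOCK,
    SessionDesign,
    StimulusSpec,
    make_stimulus_grid,
    make_trial_sequence,
)

N_CATEGORIES = 4

#: Consonant pool the operation-span letters are drawn from (no vowels, so
#: recalled sequences cannot form words; the task literature uses a similar
#: fixed pool).
OSPAN_LETTER_POOL = tuple("BCDFGHJKLNPS")


class ConfigError(ValueError):
    """Raised when a cohort/OSPAN configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Population hyperparameters of the synthetic cohort.

    Drift/boundary parameters are on the log scale (natural-log evidence
    units); ``wm_block_coupling`` is the increase of the correct-accumulator
    log-drift learning slope per OSPAN unit, the generative analogue of the
    positive WM x block interaction the analysis stages are meant to detect.
    """

    # Working-memory latent: truncated normal on the OSPAN scale.
    wm_mean: float = 45.0
    wm_sd: float = 15.0
    wm_lo: float = 0.0
    wm_hi: float = 75.0
    # Learner mixture: marginal learner probability and its WM dependence
    # (logit slope per OSPAN unit; the intercept is solved numerically so the
    # marginal rate matches ``learner_rate``).
    learner_rate: float = 0.68
    learner_wm_slope: float = 0.03
    # Learner drift trajectories (log scale).  Correct accumulator:
    # base + slope * progress - session_drop * (session - 1), with
    # progress = 5 * (session - 1) + (block - 1).
    drift_base_mean: float = 0.05
    drift_base_sd: float = 0.15
    block_slope_mean: float = 0.13
    block_slope_sd: float = 0.025
    wm_block_coupling: float = 0.003
    session_drop: float = 0.22
    # Incorrect accumulators: flat, weakly below the starting correct drift.
    incorrect_drift_mean: float = math.log(0.70)
    incorrect_drift_sd: float = 0.10
    # Boundaries (log scale), shared trajectory level across blocks.
    boundary_mean: float = math.log(1.40)
    boundary_sd: float = 0.12
    wm_boundary_coupling: float = 0.0
    # Disengaged non-learners: flat low drifts, low boundaries, WM-independent.
    nl_drift_mean: float = math.log(0.70)
    nl_drift_correct_bonus: float = 0.06
    nl_drift_sd: float = 0.08
    nl_boundary_mean: float = math.log(0.85)
    nl_boundary_sd: float = 0.10
    # Non-decision offsets delta_{i,s} (seconds, log-normal).
    delta_log_mean: float = math.log(0.33)
    delta_log_sd: float = 0.22
    n_sessions: int = 3
    blocks_per_session: int = 6

    def validate(self) -> None:
        if self.wm_sd <= 0 or self.drift_base_sd < 0 or self.boundary_sd < 0:
            raise ConfigError("scale parameters must be positive")
        if not 0.0 <= self.learner_rate <= 1.0:
            raise ConfigError("learner_rate must lie in [0, 1]")
        if self.wm_lo >= self.wm_hi:
            raise ConfigError("wm_lo must be below wm_hi")


@dataclass
class OspanConfig:
    """Recall-success model for the simulated operation-span task.

    A span of length L is recalled perfectly with probability
    ``logistic(slope * (wm - threshold[L]))``.  The default thresholds put the
    expected score close to the latent WM value across the 0-75 range, so the
    measured OSPAN score is a noisy but well-calibrated read-out of the
    latent.  Arithmetic accuracy does not gate scoring; it is simulated per
    trial with a mean of 90% for learners and 79% for disengaged
    non-learners.
    """

    recall_slope: float = 0.15
    span_thresholds: dict = field(
        default_factory=lambda: {3: 4.5, 4: 15.0, 5: 28.5, 6: 45.0, 7: 64.5}
    )
    math_acc_learner: float = 0.90
    math_acc_nonlearner: float = 0.79
    n_trials: int = 15
    span_lengths: tuple = (3, 4, 5, 6, 7)

    def validate(self) -> None:
        for p in (self.math_acc_learner, self.math_acc_nonlearner):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("arithmetic accuracies must be probabilities")
        if self.recall_slope < 0:
            raise ConfigError("recall_slope must be non-negative")
        if set(self.span_thresholds) != set(self.span_lengths):
            raise ConfigError("span_thresholds must cover every span length")


@dataclass
class ParticipantLatent:
    """Latent generative state of one synthetic participant.

    ``drift_log[session-1, d, s, block-1]`` holds log drift for accumulator d
    on stimuli of category s; ``boundary_log[session-1, d, block-1]`` the log
    boundary (response-indexed only); ``delta[s-1]`` the non-decision offset
    in seconds, constant across blocks and sessions.
    """

    participant_id: str
    wm_latent: float
    learner_flag: bool
    drift_log: np.ndarray
    boundary_log: np.ndarray
    delta: np.ndarray

    def drift(self, session: int) -> np.ndarray:
        """Drift matrix (4 responses x 4 stimuli x 6 blocks) for one session."""
        return np.exp(self.drift_log[session - 1])

    def boundary(self, session: int) -> np.ndarray:
        """Boundary matrix (4 responses x 6 blocks) for one session."""
        return np.exp(self.boundary_log[session - 1])

    def to_jsonable(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "wm_latent": float(self.wm_latent),
            "learner_flag": bool(self.learner_flag),
            "drift_log": self.drift_log.tolist(),
            "boundary_log": self.boundary_log.tolist(),
            "delta": self.delta.tolist(),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "ParticipantLatent":
        return cls(
            participant_id=d["participant_id"],
            wm_latent=float(d["wm_latent"]),
            learner_flag=bool(d["learner_flag"]),
            drift_log=np.asarray(d["drift_log"], dtype=float),
            boundary_log=np.asarray(d["boundary_log"], dtype=float),
            delta=np.asarray(d["delta"], dtype=float),
        )


def save_cohort(cohort: list[ParticipantLatent], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_jsonable() for p in cohort], fh)


def load_cohort(path) -> list[ParticipantLatent]:
    with open(path) as fh:
        return [ParticipantLatent.from_jsonable(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _logistic(x):
    return stats.logistic.cdf(x)


def _solve_learner_intercept(config: CohortConfig) -> float:
    """Intercept of the learner logit so the marginal learner rate matches config.

    Integrates the logistic over the truncated-normal WM distribution by
    Gauss-Legendre quadrature and solves for the intercept by bisection.
    """
    nodes, weights = np.polynomial.legendre.leggauss(80)
    lo, hi = config.wm_lo, config.wm_hi
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    a = (lo - config.wm_mean) / config.wm_sd
    b = (hi - config.wm_mean) / config.wm_sd
    dens = stats.truncnorm.pdf(x, a, b, loc=config.wm_mean, scale=config.wm_sd)
    w = weights * 0.5 * (hi - lo) * dens
    w = w / w.sum()
    centered = config.learner_wm_slope * (x - config.wm_mean)

    def marginal(l0):
        return float(np.sum(w * _logistic(l0 + centered))) - config.learner_rate

    if config.learner_rate <= 0.0:
        return -np.inf
    if config.learner_rate >= 1.0:
        return np.inf
    return float(optimize.brentq(marginal, -30.0, 30.0))


def sample_cohort(
    n_participants: int,
    config: CohortConfig | None = None,
    rng_seed: int = 0,
) -> list[ParticipantLatent]:
    """Draw a cohort of latent participants from the population model."""
    config = config or CohortConfig()
    config.validate()
    n_blocks = config.blocks_per_session
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2024]))
    a = (config.wm_lo - config.wm_mean) / config.wm_sd
    b = (config.wm_hi - config.wm_mean) / config.wm_sd
    wm = stats.truncnorm.rvs(
        a, b, loc=config.wm_mean, scale=config.wm_sd, size=n_participants, random_state=rng
    )
    l0 = _solve_learner_intercept(config)
    p_learner = _logistic(l0 + config.learner_wm_slope * (wm - config.wm_mean))
    learner = rng.random(n_participants) < p_learner

    blocks = np.arange(n_blocks, dtype=float)  # 0-based within session
    cohort: list[ParticipantLatent] = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        drift_log = np.empty((config.n_sessions, N_CATEGORIES, N_CATEGORIES, n_blocks))
        boundary_log = np.empty((config.n_sessions, N_CATEGORIES, n_blocks))
        if learner[i]:
            base = rng.normal(config.drift_base_mean, config.drift_base_sd, size=N_CATEGORIES)
            slope = (
                config.block_slope_mean
                + config.wm_block_coupling * (wm[i] - config.wm_mean)
                + rng.normal(0.0, config.block_slope_sd, size=N_CATEGORIES)
            )
            incorrect = rng.normal(
                config.incorrect_drift_mean, config.incorrect_drift_sd,
                size=(N_CATEGORIES, N_CATEGORIES),
            )
            blevel = (
                config.boundary_mean
                + config.wm_boundary_coupling * (wm[i] - config.wm_mean)
                + rng.normal(0.0, config.boundary_sd, size=N_CATEGORIES)
            )
            for sess in range(config.n_sessions):
                progress = 5.0 * sess + blocks
                for s in range(N_CATEGORIES):
                    drift_log[sess, :, s, :] = incorrect[:, s, None]
                    drift_log[sess, s, s, :] = (
                        base[s] + slope[s] * progress - config.session_drop * sess
                    )
                boundary_log[sess] = np.repeat(blevel[:, None], n_blocks, axis=1)
        else:
            flat = rng.normal(
                config.nl_drift_mean, config.nl_drift_sd,
                size=(N_CATEGORIES, N_CATEGORIES),
            )
            flat[np.diag_indices(N_CATEGORIES)] += config.nl_drift_correct_bonus
            blevel = rng.normal(config.nl_boundary_mean, config.nl_boundary_sd, size=N_CATEGORIES)
            for sess in range(config.n_sessions):
                drift_log[sess] = np.repeat(flat[:, :, None], n_blocks, axis=2)
                boundary_log[sess] = np.repeat(blevel[:, None], n_blocks, axis=1)
        delta = np.exp(rng.normal(config.delta_log_mean, config.delta_log_sd, size=N_CATEGORIES))
        cohort.append(
            ParticipantLatent(
                participant_id=pid,
                wm_latent=float(wm[i]),
                learner_flag=bool(learner[i]),
                drift_log=drift_log,
                boundary_log=boundary_log,
                delta=delta,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# race simulation
# ---------------------------------------------------------------------------

def sample_ig_first_passage(mu: float, b: float, rng: np.random.Generator, size=None):
    """Exact draw(s) of the first-passage time of a drift-``mu`` Wiener process to ``b``.

    Uses the transform-method inverse-Gaussian sampler (mean ``b/mu``, shape
    ``b^2``) provided by :meth:`numpy.random.Generator.wald`.
    """
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(mu <= 0.0) or np.any(b <= 0.0):
        raise ValueError("mu and b must be strictly positive")
    return rng.wald(b / mu, b * b, size=size)


def simulate_trial(
    latent: ParticipantLatent,
    session: int,
    block,
    stimulus: StimulusSpec,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Race one trial: four accumulators, first passage wins.

    Generalization-block trials (block "G") use the final training block's
    parameters; the trajectories are block-resolution and no within-block
    learning is modelled.
    """
    bl = latent.drift_log.shape[-1] - 1 if block == GENERALIZATION_BLOCK else int(block) - 1
    s = stimulus.tone_category - 1
    mu = np.exp(latent.drift_log[session - 1, :, s, bl])
    bnd = np.exp(latent.boundary_log[session - 1, :, bl])
    times = sample_ig_first_passage(mu, bnd, rng)
    d = int(np.argmin(times))  # ties are measure-zero; argmin takes the lowest index
    return d + 1, float(latent.delta[s] + times[d])


def simulate_experiment(
    cohort: list[ParticipantLatent],
    design: SessionDesign | None = None,
    rng_seed: int = 0,
    grid: list[StimulusSpec] | None = None,
) -> pd.DataFrame:
    """Simulate the full three-session experiment for every participant.

    Returns one row per scheduled trial with columns
    ``participant_id, session, block, trial_index, tone_category, speaker_id,
    syllable, response, rt, feedback, correct``.  ``block`` is "1".."6" or
    "G" (stored as string so training and generalization share one column).
    """
    design = design or SessionDesign()
    grid = grid or make_stimulus_grid()
    root = np.random.SeedSequence([rng_seed, 77])
    child_seeds = root.spawn(len(cohort))
    rows = []
    for latent, seedseq in zip(cohort, child_seeds):
        rng = np.random.default_rng(seedseq)
        order_seed = int(rng.integers(2**31))
        for session in range(1, design.n_sessions + 1):
            seq = make_trial_sequence(design, grid, session, order_seed)
            # vectorised race over the session's trial slots
            s_idx = np.array([stim.tone_category - 1 for _, stim, _ in seq])
            bl_idx = np.array(
                [design.blocks_per_session - 1 if blk == GENERALIZATION_BLOCK else int(blk) - 1
                 for blk, _, _ in seq]
            )
            mu = np.exp(latent.drift_log[session - 1][:, s_idx, bl_idx]).T  # (n_trials, 4)
            bnd = np.exp(latent.boundary_log[session - 1][:, bl_idx]).T
            times = rng.wald(bnd / mu, bnd * bnd)
            resp = np.argmin(times, axis=1)
            rt = latent.delta[s_idx] + times[np.arange(len(seq)), resp]
            for k, (blk, stim, fb) in enumerate(seq):
                rows.append(
                    (
                        latent.participant_id,
                        session,
                        str(blk),
                        k + 1,
                        stim.tone_category,
                        stim.speaker_id,
                        stim.syllable,
                        int(resp[k]) + 1,
                        float(rt[k]),
                        fb,
                        int(resp[k]) + 1 == stim.tone_category,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "session", "block", "trial_index", "tone_category",
            "speaker_id", "syllable", "response", "rt", "feedback", "correct",
        ],
    )


# ---------------------------------------------------------------------------
# operation span simulation
# ---------------------------------------------------------------------------

def simulate_ospan(
    latent: ParticipantLatent,
    config: OspanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[dict], int]:
    """Simulate one participant's 15-trial operation-span task.

    Returns the trial records and the resulting OSPAN score (sum of span
    lengths of perfectly recalled trials, computed with
    :func:`tonelearn.behavior_metrics.ospan_score`).
    """
    from .behavior_metrics import ospan_score

    config = config or OspanConfig()
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    lengths = np.repeat(config.span_lengths, config.n_trials // len(config.span_lengths))
    rng.shuffle(lengths)
    math_acc = config.math_acc_learner if latent.learner_flag else config.math_acc_nonlearner
    records: list[dict] = []
    for k, length in enumerate(lengths, start=1):
        presented = list(rng.choice(OSPAN_LETTER_POOL, size=length, replace=False))
        p_recall = _logistic(
            config.recall_slope * (latent.wm_latent - config.span_thresholds[int(length)])
        )
        if rng.random() < p_recall:
            recalled = list(presented)
        else:
            recalled = list(presented)
            if length >= 2 and rng.random() < 0.5:
                j = int(rng.integers(length - 1))  # transpose two adjacent letters
                recalled[j], recalled[j + 1] = recalled[j + 1], recalled[j]
            else:
                recalled = recalled[: max(0, length - 1 - int(rng.integers(2)))]
        records.append(
            {
                "trial_index": k,
                "span_length": int(length),
                "presented_letters": "".join(presented),
                "recalled_letters": "".join(recalled),
                "n_math_correct": int(rng.binomial(int(length), math_acc)),
            }
        )
    return records, ospan_score(records)


def simulate_cohort_ospan(
    cohort: list[ParticipantLatent],
    config: OspanConfig | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OSPAN tables for a whole cohort: (trial-level records, per-participant scores)."""
    root = np.random.SeedSequence([rng_seed, 303])
    trials = []
    scores = []
    for latent, seedseq in zip(cohort, root.spawn(len(cohort))):
        recs, score = simulate_ospan(latent, config, np.random.default_rng(seedseq))
        for r in recs:
            trials.append({"participant_id": latent.participant_id, **r})
        scores.append(
            {
                "participant_id": latent.participant_id,
                "ospan_score": score,
                "wm_latent": latent.wm_latent,
                "learner_flag_true": latent.learner_flag,
            }
        )
    return pd.DataFrame(trials), pd.DataFrame(scores)
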