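"""Race-model likelihood: total probability, limits, and simulation identities."""

import numpy as np
import pytest
from scipy import integrate, stats

from tonelearn.race_ddm import ig_pdf, ig_sf, race_loglik
from tonelearn.synthetic_cohort import ParticipantLatent, simulate_trial
from tonelearn.task_design import make_stimulus_grid


def slow_reference_loglik(rt, response, mu, b, delta):
    """Direct unvectorized evaluation via scipy's inverse-Gaussian distribution."""
    tau = rt - delta
    if tau <= 0:
        return -np.inf
    total = 0.0
    for d in range(4):
        lam = b[d] * b[d]
        m = (b[d] / mu[d]) / lam
        if d == response - 1:
            total += stats.invgauss.logpdf(tau, m, scale=lam)
        else:
            total += stats.invgauss.logsf(tau, m, scale=lam)
    return total


def race_choice_prob_quadrature(mu, b, d):
    """P(response d) = int f_d(t) prod_{d' != d} S_{d'}(t) dt."""

    def integrand(t):
        val = float(ig_pdf(t, mu[d], b[d]))
        for dd in range(len(mu)):
            if dd != d:
                val *= float(ig_sf(t, mu[dd], b[dd]))
        return val

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def test_loglik_matches_slow_reference():
    rng = np.random.default_rng(5)
    for _ in range(50):
        mu = rng.uniform(0.3, 3.0, 4)
        b = rng.uniform(0.5, 2.5, 4)
        delta = rng.uniform(0.1, 0.4)
        rt = delta + rng.uniform(0.05, 3.0)
        resp = int(rng.integers(1, 5))
        trial = {"rt": rt, "response": resp, "tone_category": 1}
        got = race_loglik(trial, mu, b, delta)
        want = slow_reference_loglik(rt, resp, mu, b, delta)
        assert got == pytest.approx(want, abs=1e-10)


def test_total_probability_sums_to_one():
    mu = np.array([1.4, 0.8, 0.6, 1.0])
    b = np.array([1.2, 0.9, 1.5, 1.1])
    total = sum(race_choice_prob_quadrature(mu, b, d) for d in range(4))
    assert total == pytest.approx(1.0, abs=1e-6)


def test_degenerate_single_accumulator_reduces_to_ig_density():
    mu = np.array([1.5, 1e-8, 1e-8, 1e-8])
    b = np.array([1.0, 50.0, 50.0, 50.0])
    trial = {"rt": 1.1, "response": 1, "tone_category": 1}
    got = race_loglik(trial, mu, b, 0.3)
    assert got == pytest.approx(float(np.log(ig_pdf(0.8, 1.5, 1.0))), abs=1e-6)


def test_rt_below_offset_gives_minus_inf_not_exception():
    trial = {"rt": 0.2, "response": 2, "tone_category": 1}
    assert race_loglik(trial, np.ones(4), np.ones(4), 0.3) == -np.inf


def _latent_with(mu_matrix, b_vec, delta=0.3):
    drift_log = np.tile(np.log(np.asarray(mu_matrix))[None, :, :, None], (3, 1, 1, 6))
    boundary_log = np.tile(np.log(np.asarray(b_vec))[None, :, None], (3, 1, 6))
    return ParticipantLatent(
        participant_id="T",
        wm_latent=45.0,
        learner_flag=True,
        drift_log=drift_log,
        boundary_log=boundary_log,
        delta=np.full(4, delta),
    )


def test_symmetric_race_uniform_choice(rng):
    latent = _latent_with(np.full((4, 4), 1.0), np.full(4, 1.0))
    stim = [s for s in make_stimulus_grid() if s.tone_category == 2][0]
    resp = np.array([simulate_trial(latent, 1, 3, stim, rng)[0] for _ in range(8000)])
    freqs = np.bincount(resp, minlength=5)[1:] / len(resp)
    np.testing.assert_allclose(freqs, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / len(resp)) + 0.005)


def test_dominant_drift_wins(rng):
    # dominance limit: competitors have both negligible drift and high boundaries
    mu = np.full((4, 4), 0.02)
    mu[2, 2] = 5.0
    latent = _latent_with(mu, np.array([3.0, 3.0, 1.0, 3.0]))
    stim = [s for s in make_stimulus_grid() if s.tone_category == 3][0]
    resp, rts = zip(*(simulate_trial(latent, 1, 1, stim, rng) for _ in range(500)))
    assert np.mean(np.array(resp) == 3) > 0.99
    assert min(rts) > 0.3  # rt always exceeds the offset


def test_simulated_choice_frequencies_match_quadrature(rng):
    """Race identity: Monte Carlo choice rates equal quadrature of f_d prod S_d'."""
    mu = np.array([1.8, 0.9, 0.7, 1.2])
    b = np.array([1.1, 1.3, 0.8, 1.0])
    n = 100_000
    times = rng.wald(b / mu, b * b, size=(n, 4))
    sim = np.bincount(times.argmin(axis=1), minlength=4) / n
    for d in range(4):
        p = race_choice_prob_quadrature(mu, b, d)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(sim[d] - p) < 3 * se + 1e-4


def test_speed_accuracy_tradeoff(rng):
    """Raising all boundaries jointly (response caution) slows RT and raises accuracy."""
    mu = np.array([1.5, 0.8, 0.8, 0.8])

    def run(b_all):
        b = np.full(4, b_all)
        t = rng.wald(b / mu, b * b, size=(40_000, 4))
        resp = t.argmin(axis=1)
        return (resp == 0).mean(), t.min(axis=1).mean()

    acc_lo, rt_lo = run(0.8)
    acc_hi, rt_hi = run(1.6)
    assert acc_hi > acc_lo
    assert rt_hi > rt_lo


def test_single_boundary_handicaps_its_own_accumulator(rng):
    """Raising one competitor's boundary slows everyone and favours the others."""
    mu = np.array([1.5, 0.8, 0.8, 0.8])

    def run(b_wrong):
        b = np.array([1.0, b_wrong, 1.0, 1.0])
        t = rng.wald(b / mu, b * b, size=(40_000, 4))
        return (t.argmin(axis=1) == 0).mean(), t.min(axis=1).mean()

    acc_lo, rt_lo = run(1.0)
    acc_hi, rt_hi = run(2.0)
    assert acc_hi > acc_lo
    assert rt_hi > rt_lo


def test_higher_correct_drift_faster_and_more_accurate(rng):
    def run(mu_c):
        mu = np.array([mu_c, 0.8, 0.8, 0.8])
        b = np.full(4, 1.2)
        t = rng.wald(b / mu, b * b, size=(40_000, 4))
        resp = t.argmin(axis=1)
        correct = resp == 0
        return correct.mean(), t.min(axis=1)[correct].mean()

    acc_lo, rt_lo = run(1.0)
    acc_hi, rt_hi = run(2.0)
    assert acc_hi > acc_lo
    assert rt_hi < rt_lo


def test_average_loglik_maximized_near_generating_drift(rng):
    """1-D sweep of the correct drift: data-average log-likelihood peaks near truth."""
    true_mu = np.array([1.6, 0.8, 0.8, 0.8])
    b = np.full(4, 1.2)
    delta = 0.3
    n = 4000
    times = rng.wald(b / true_mu, b * b, size=(n, 4))
    resp = times.argmin(axis=1) + 1
    rts = delta + times.min(axis=1)
    grid = np.linspace(0.8, 2.8, 21)
    avg = []
    for m in grid:
        mu = np.array([m, 0.8, 0.8, 0.8])
        ll = [
            race_loglik({"rt": rts[i], "response": int(resp[i]), "tone_category": 1}, mu, b, delta)
            for i in range(n)
        ]
        avg.append(np.mean(ll))
    best = grid[int(np.argmax(avg))]
    assert abs(best - 1.6) <= 0.2
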