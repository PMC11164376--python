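"""Hierarchical race-model fitting: accounting, summaries, predictive checks."""

import numpy as np
import pandas as pd
import pytest

from tonelearn.race_ddm import (
    RaceDDM,
    correct_drift_summary,
    fit_session,
    posterior_predictive_check,
)


@pytest.fixture(scope="module")
def tiny_fit(session1_trimmed_module):
    model = RaceDDM(n_iter=240, burn_in=80, thin=4, random_state=1)
    model.fit(session1_trimmed_module)
    return model


@pytest.fixture(scope="module")
def session1_trimmed_module():
    from tonelearn.behavior_metrics import trim_rt
    from tonelearn.synthetic_cohort import sample_cohort, simulate_experiment

    cohort = sample_cohort(5, rng_seed=9)
    trials = simulate_experiment(cohort, rng_seed=10)
    return trim_rt(trials[trials["session"] == 1])


def test_retained_draw_accounting(tiny_fit):
    fit = tiny_fit.fit_
    assert fit.mcmc_config["n_retained"] == (240 - 80) // 4
    assert fit.draws["mu"].shape[0] == 40
    # the study's default schedule retains (6000 - 2000) / 5 draws
    default = RaceDDM()
    assert (default.n_iter - default.burn_in) // default.thin == 800


def test_posterior_mean_within_pointwise_ci(tiny_fit):
    fit = tiny_fit.fit_
    for name in ("mu", "b", "delta", "mu_pop", "b_pop"):
        lo, hi = fit.ci95[name]
        pm = getattr(fit.posterior_mean, name)
        assert (pm >= lo - 1e-9).all() and (pm <= hi + 1e-9).all()


def test_all_parameters_strictly_positive(tiny_fit):
    pm = tiny_fit.fit_.posterior_mean
    for arr in (pm.mu, pm.b, pm.delta, pm.mu_pop, pm.b_pop):
        assert (arr > 0).all()


def test_fit_session_wrapper(session1_trimmed_module):
    fit = fit_session(
        session1_trimmed_module, {"n_iter": 120, "burn_in": 40, "thin": 4}, rng_seed=3
    )
    assert fit.mcmc_config["n_retained"] == 20
    assert fit.session == 1


def test_generalization_excluded_by_default(small_trials):
    model = RaceDDM(n_iter=60, burn_in=20, thin=2, random_state=0)
    s1 = small_trials[small_trials["session"] == 1]
    pids, i_arr, s_arr, d_arr, bl_arr, rt = model._encode(s1)
    assert len(rt) == small_trials["participant_id"].nunique() * 240
    model_g = RaceDDM(include_generalization=True)
    _, _, _, _, _, rt_g = model_g._encode(s1)
    assert len(rt_g) == small_trials["participant_id"].nunique() * 280


def test_correct_drift_summary_is_plain_average(tiny_fit):
    fit = tiny_fit.fit_
    summ = correct_drift_summary(fit)
    assert len(summ) == len(fit.participants) * 6
    i, bl = 0, 2
    manual = np.mean([fit.posterior_mean.mu[i, s, s, bl] for s in range(4)])
    got = summ[(summ["participant_id"] == fit.participants[i]) & (summ["block"] == bl + 1)]
    assert got["drift"].iloc[0] == pytest.approx(manual, rel=1e-12)
    manual_b = fit.posterior_mean.b[i, :, bl].mean()
    assert got["boundary"].iloc[0] == pytest.approx(manual_b, rel=1e-12)


def test_empty_cells_warn_not_fail():
    rng = np.random.default_rng(0)
    n = 120
    df = pd.DataFrame(
        {
            "participant_id": ["A"] * n + ["B"] * n,
            "session": 1,
            "block": [str(b) for b in rng.integers(1, 7, 2 * n)],
            "tone_category": np.r_[rng.integers(1, 4, n), rng.integers(1, 5, n)],  # A never hears tone 4
            "response": rng.integers(1, 5, 2 * n),
            "rt": rng.uniform(0.5, 2.0, 2 * n),
        }
    )
    df["correct"] = df["response"] == df["tone_category"]
    with pytest.warns(UserWarning, match="no trials"):
        RaceDDM(n_iter=40, burn_in=10, thin=2, random_state=0).fit(df)


def test_invalid_schedules_rejected(session1_trimmed_module):
    with pytest.raises(ValueError):
        RaceDDM(n_iter=100, burn_in=100).fit(session1_trimmed_module)
    with pytest.raises(ValueError):
        RaceDDM().fit(pd.DataFrame({"participant_id": [], "block": [], "tone_category": [],
                                    "response": [], "rt": []}))


def test_ppc_covers_self_generated_data(tiny_fit, session1_trimmed_module):
    ppc = posterior_predictive_check(tiny_fit.fit_, session1_trimmed_module, n_rep=100, rng_seed=0)
    assert ppc["covered"].mean() >= 0.9


def test_ppc_detects_shifted_rts(tiny_fit, session1_trimmed_module):
    shifted = session1_trimmed_module.copy()
    shifted["rt"] = shifted["rt"] + 1.0
    ppc = posterior_predictive_check(tiny_fit.fit_, shifted, n_rep=100, rng_seed=0)
    med = ppc[ppc["statistic"] == "rt_q50"]
    assert not med["covered"].any()


def test_sklearn_param_interface():
    model = RaceDDM(n_iter=300, thin=3)
    params = model.get_params()
    assert params["n_iter"] == 300 and params["thin"] == 3
    model.set_params(burn_in=100)
    assert model.burn_in == 100
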