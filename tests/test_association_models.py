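"""Association models: WM effects on accuracy, maintenance, generalization, DDM parameters."""

import numpy as np
import pandas as pd
import pytest

from tonelearn.behavior_metrics import metrics_table
from tonelearn.synthetic_cohort import (
    CohortConfig,
    sample_cohort,
    simulate_cohort_ospan,
    simulate_experiment,
)
from tonelearn.wm_association import (
    accuracy_model,
    ddm_parameter_model,
    generalization_model,
    maintenance_model,
)


def _cohort_tables(n, cfg, seed):
    cohort = sample_cohort(n, cfg, rng_seed=seed)
    trials = simulate_experiment(cohort, rng_seed=seed + 1)
    _, scores = simulate_cohort_ospan(cohort, rng_seed=seed + 2)
    return cohort, metrics_table(trials, scores), scores


@pytest.fixture(scope="module")
def coupled_cohort():
    return _cohort_tables(100, CohortConfig(), seed=42)


def test_accuracy_model_recovers_wm_block_interaction(coupled_cohort):
    """Generative WM x block coupling appears as a positive OSPAN:Block coefficient."""
    _, tables, scores = coupled_cohort
    res = accuracy_model(tables["accuracy"], scores)
    b, se, p = res["OSPAN:Block"]
    assert b > 0 and b / se > 2.0
    assert res.n_participants == 100
    assert res.n_obs == 100 * 18


def test_accuracy_model_table_structure(coupled_cohort):
    _, tables, scores = coupled_cohort
    res = accuracy_model(tables["accuracy"], scores)
    expected = {
        "Intercept", "OSPAN", "Block", "Session2", "Session3",
        "OSPAN:Block", "OSPAN:Session2", "OSPAN:Session3",
        "Block:Session2", "Block:Session3",
        "OSPAN:Block:Session2", "OSPAN:Block:Session3",
    }
    assert set(res.terms) == expected


def test_accuracy_model_learners_only(coupled_cohort):
    cohort, tables, scores = coupled_cohort
    res = accuracy_model(tables["accuracy"], scores, tables["participants"], learners_only=True)
    n_learn = (tables["participants"]["learner_class"] == "learner").sum()
    assert res.n_participants == n_learn
    b, se, _ = res["OSPAN:Block"]
    assert b > 0


def test_null_cohort_ospan_terms_mostly_insignificant():
    """Type-I calibration: without WM coupling, OSPAN terms stay within 2 SE."""
    hits = 0
    checks = 0
    for seed in range(10):
        cfg = CohortConfig(wm_block_coupling=0.0, learner_wm_slope=0.0)
        _, tables, scores = _cohort_tables(40, cfg, seed=500 + 3 * seed)
        res = accuracy_model(tables["accuracy"], scores)
        for term in ("OSPAN", "OSPAN:Block"):
            b, se, _ = res[term]
            checks += 1
            hits += abs(b / se) < 2.0
    assert hits / checks >= 0.8


def test_maintenance_model_null_wm(coupled_cohort):
    """Maintenance deltas carry no WM dependence by construction."""
    _, tables, scores = coupled_cohort
    res = maintenance_model(tables["maintenance"], scores, tables["participants"])
    b, se, _ = res["OSPAN"]
    assert abs(b / se) < 3.0
    assert {"Time2to3", "NoDelay", "OSPAN:NoDelay", "OSPAN:Time2to3:NoDelay"} <= set(res.terms)


def test_generalization_model_null_wm(coupled_cohort):
    _, tables, scores = coupled_cohort
    res = generalization_model(tables["generalization"], scores, tables["participants"])
    b, se, _ = res["OSPAN"]
    assert abs(b / se) < 3.0
    assert "OSPAN:Session2" in res.terms and "OSPAN:Session3" in res.terms


def test_ddm_parameter_model_on_drift_summaries():
    """WM-coupled drift summaries yield a positive OSPAN-related coefficient.

    Uses latent (generator) drifts in place of a fitted posterior so the test
    isolates the association stage from MCMC noise.
    """
    cohort = sample_cohort(80, CohortConfig(), rng_seed=77)
    _, scores = simulate_cohort_ospan(cohort, rng_seed=78)
    rows = []
    for p in cohort:
        diag = np.exp(p.drift_log[0][range(4), range(4), :]).mean(axis=0)
        for bl in range(6):
            rows.append({"participant_id": p.participant_id, "session": 1,
                         "block": bl + 1, "drift": diag[bl],
                         "boundary": float(np.exp(p.boundary_log[0]).mean())})
    summ = pd.DataFrame(rows)
    learners = pd.DataFrame(
        {"participant_id": [p.participant_id for p in cohort],
         "learner_class": ["learner" if p.learner_flag else "non_learner" for p in cohort]}
    )
    res = ddm_parameter_model(summ, scores, "drift", learners)
    b, se, _ = res["OSPAN:Block"]
    assert b > 0 and b / se > 2.0
    res_b = ddm_parameter_model(summ, scores, "boundary", learners)
    bb, sb, _ = res_b["OSPAN"]
    assert abs(bb / sb) < 3.0  # boundaries are WM-independent by construction


def test_constant_outcome_degenerates_cleanly(coupled_cohort):
    _, tables, scores = coupled_cohort
    acc = tables["accuracy"].copy()
    acc["accuracy_pct"] = 50.0
    res = accuracy_model(acc, scores)
    assert res.beta[res.terms.index("Intercept")] == pytest.approx(50.0, abs=1e-6)
    for term in res.terms[1:]:
        b, _, _ = res[term]
        assert b == pytest.approx(0.0, abs=1e-6)


def test_invalid_parameter_name_rejected(coupled_cohort):
    _, tables, scores = coupled_cohort
    with pytest.raises(ValueError):
        ddm_parameter_model(pd.DataFrame(), scores, "speed")
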