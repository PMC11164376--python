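"""Deterministic behavioral scoring: trimming, accuracy, classification, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonelearn.behavior_metrics import (
    LEARNER_CUTOFF_PCT,
    block_accuracy,
    classify_learner,
    classify_learners,
    generalization_score,
    maintenance_scores,
    median_split,
    metrics_table,
    ospan_score,
    trim_rt,
)


def brute_force_trim(rts, tail):
    """Sort-and-slice oracle: keep values within the pooled [q, 1-q] quantiles."""
    lo, hi = np.quantile(rts, [tail, 1 - tail])
    return [r for r in rts if lo <= r <= hi]


def _trials_from_rts(rts):
    return pd.DataFrame(
        {
            "participant_id": "P1",
            "session": 1,
            "block": "1",
            "tone_category": 1,
            "response": 1,
            "rt": rts,
            "correct": True,
        }
    )


def test_trim_removes_one_percent_per_tail():
    rng = np.random.default_rng(0)
    rts = rng.uniform(0.3, 3.0, 10_000)
    out = trim_rt(_trials_from_rts(rts), tail=0.01)
    assert len(out) == 9_800


def test_trim_identity_and_tie_cases():
    df = _trials_from_rts(np.linspace(0.5, 1.5, 100))
    assert len(trim_rt(df, tail=0.0)) == 100
    ties = _trials_from_rts(np.full(50, 0.7))
    assert len(trim_rt(ties, tail=0.01)) == 50  # identical RTs: nothing removed


def test_trim_warns_on_empty():
    with pytest.warns(UserWarning):
        out = trim_rt(_trials_from_rts(np.array([])), tail=0.01)
    assert len(out) == 0


@given(
    rts=st.lists(st.floats(0.2, 5.0, allow_nan=False), min_size=10, max_size=300),
    tail=st.sampled_from([0.01, 0.02, 0.05]),
)
@settings(max_examples=50, deadline=None)
def test_trim_agrees_with_sort_oracle(rts, tail):
    out = trim_rt(_trials_from_rts(np.array(rts)), tail=tail)
    assert sorted(out["rt"]) == sorted(brute_force_trim(np.array(rts), tail))


def test_block_accuracy_arithmetic_and_oracle(rng):
    n = 400
    df = pd.DataFrame(
        {
            "participant_id": rng.choice(["A", "B"], n),
            "session": rng.choice([1, 2], n),
            "block": rng.choice(["1", "2", "G"], n),
            "tone_category": rng.integers(1, 5, n),
            "response": rng.integers(1, 5, n),
            "rt": rng.uniform(0.4, 2.0, n),
        }
    )
    df["correct"] = df["response"] == df["tone_category"]
    acc = block_accuracy(df)
    # brute-force recount, no groupby
    for _, row in acc.iterrows():
        sub = df[
            (df["participant_id"] == row["participant_id"])
            & (df["session"] == row["session"])
            & (df["block"] == row["block"])
        ]
        assert row["n_trials"] == len(sub)
        assert row["accuracy_pct"] == pytest.approx(100.0 * sub["correct"].mean())
    # row-order invariance
    acc2 = block_accuracy(df.sample(frac=1.0, random_state=1))
    pd.testing.assert_frame_equal(acc, acc2)


def test_chance_level_arithmetic():
    df = _trials_from_rts(np.full(40, 1.0))
    df["correct"] = [True] * 10 + [False] * 30
    assert block_accuracy(df)["accuracy_pct"].iloc[0] == 25.0


@pytest.mark.parametrize(
    "acc,label",
    [(35.0, "non_learner"), (37.5, "learner"), (25.0, "non_learner"),
     (0.0, "non_learner"), (35.01, "learner")],
)
def test_learner_classification_boundary(acc, label):
    assert classify_learner(acc) == label


def test_classify_learners_flags_missing_final_block():
    acc = pd.DataFrame(
        {
            "participant_id": ["A", "A", "B"],
            "session": [3, 3, 2],
            "block": ["6", "1", "6"],
            "accuracy_pct": [50.0, 30.0, 80.0],
        }
    )
    out = classify_learners(acc).set_index("participant_id")["learner_class"]
    assert out.loc["A"] == "learner"
    assert pd.isna(out.loc["B"])
    assert LEARNER_CUTOFF_PCT == 35.0


def _rec(length, presented, recalled, n_math=0):
    return {
        "span_length": length,
        "presented_letters": presented,
        "recalled_letters": recalled,
        "n_math_correct": n_math,
    }


def test_ospan_scoring_rules():
    # a perfectly recalled length-4 span contributes exactly 4 points
    assert ospan_score([_rec(4, "AIDF", "AIDF")]) == 4
    # partial or reordered recalls contribute nothing; order matters
    assert ospan_score([_rec(3, "BCD", "BCD"), _rec(4, "FGHJ", "FGHJ"),
                        _rec(5, "KLNPS", "KLNSP")]) == 7
    assert ospan_score([_rec(4, "AIDF", "ADIF")]) == 0
    assert ospan_score([_rec(4, "AIDF", "AID")]) == 0
    # full recall across 15 trials of spans 3-7 gives the 75 maximum
    full = [_rec(ln, "ABCDEFG"[:ln], "ABCDEFG"[:ln]) for ln in (3, 4, 5, 6, 7) for _ in range(3)]
    assert ospan_score(full) == 75


def test_ospan_malformed_record_rejected():
    with pytest.raises(ValueError):
        ospan_score([_rec(4, "ABC", "ABC")])


def _acc_table(values):
    rows = []
    for (pid, session, block), v in values.items():
        rows.append({"participant_id": pid, "session": session, "block": block,
                     "accuracy_pct": v})
    return pd.DataFrame(rows)


def test_maintenance_deltas():
    acc = _acc_table(
        {
            ("A", 1, "5"): 55.0, ("A", 1, "6"): 60.0, ("A", 2, "1"): 50.0,
            ("A", 2, "5"): 62.0, ("A", 2, "6"): 62.0, ("A", 3, "1"): 58.0,
        }
    )
    out = maintenance_scores(acc).set_index(["transition", "delay_type"])["delta_pct"]
    assert out.loc[("1to2", "no_delay")] == pytest.approx(5.0)
    assert out.loc[("1to2", "delay")] == pytest.approx(-10.0)
    assert out.loc[("2to3", "no_delay")] == pytest.approx(0.0)
    assert out.loc[("2to3", "delay")] == pytest.approx(-4.0)


def test_maintenance_missing_blocks_give_missing_deltas():
    acc = _acc_table({("A", 1, "6"): 60.0})
    out = maintenance_scores(acc)
    assert out["delta_pct"].isna().all()


def test_generalization_score_subtraction():
    acc = _acc_table({("A", 1, "6"): 58.0, ("A", 1, "G"): 55.0,
                      ("B", 1, "6"): 40.0, ("B", 1, "G"): 40.0})
    out = generalization_score(acc).set_index("participant_id")["generalization_score_pct"]
    assert out.loc["A"] == pytest.approx(-3.0)
    assert out.loc["B"] == pytest.approx(0.0)


def test_median_split_ties_go_high():
    scores = pd.DataFrame({"participant_id": ["A", "B", "C"], "ospan_score": [10, 46, 50]})
    out = median_split(scores).set_index("participant_id")["wm_group"]
    assert out.loc["A"] == "low" and out.loc["B"] == "high" and out.loc["C"] == "high"
    allsame = pd.DataFrame({"participant_id": list("ABCD"), "ospan_score": [40] * 4})
    assert (median_split(allsame)["wm_group"] == "high").all()
    with pytest.raises(ValueError):
        median_split(pd.DataFrame({"participant_id": ["A"], "ospan_score": [5]}))


def test_metrics_table_end_to_end(small_trials, small_ospan):
    _, scores = small_ospan
    tables = metrics_table(small_trials, scores)
    assert set(tables) == {"accuracy", "participants", "maintenance", "generalization"}
    parts = tables["participants"]
    assert {"learner_class", "ospan_score", "wm_group"} <= set(parts.columns)
    assert len(parts) == small_trials["participant_id"].nunique()


def test_maintenance_reflects_generated_forgetting():
    """Cohort generated with a session-start drop: delay deltas negative, no-delay near zero."""
    from tonelearn.synthetic_cohort import CohortConfig, sample_cohort, simulate_experiment

    cohort = sample_cohort(60, CohortConfig(), rng_seed=21)
    trials = simulate_experiment(cohort, rng_seed=22)
    learners = {p.participant_id for p in cohort if p.learner_flag}
    acc = block_accuracy(trials[trials["participant_id"].isin(learners)])
    deltas = maintenance_scores(acc)
    mean_by = deltas.groupby("delay_type")["delta_pct"].mean()
    assert mean_by.loc["delay"] < -3.0
    assert abs(mean_by.loc["no_delay"]) < 8.0  # within-session change stays modest
    assert mean_by.loc["delay"] < mean_by.loc["no_delay"] - 5.0


def test_generalization_null_when_parameters_shared():
    """Training and generalization stimuli share latent parameters: mean score near 0."""
    from tonelearn.synthetic_cohort import CohortConfig, sample_cohort, simulate_experiment

    cohort = sample_cohort(60, CohortConfig(), rng_seed=31)
    trials = simulate_experiment(cohort, rng_seed=32)
    scores = generalization_score(block_accuracy(trials))
    assert abs(scores["generalization_score_pct"].mean()) < 3.0
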