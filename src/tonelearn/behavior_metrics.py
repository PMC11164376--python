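"""Deterministic behavioral computations.

RT trimming, block accuracy tables, learner classification, operation-span
scoring, maintenance and generalization scores, and the median-split
working-memory grouping.  All functions are pure transformations of tidy
trial/metrics tables and are invariant to input row order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .task_design import GENERALIZATION_BLOCK

#: Final-block accuracy (percent) at or below which a participant is a
#: non-learner.  The study's chance-based cutoff for 40 trials at p=0.25,
#: stated as 25% +/- 10%; stored as a constant rather than recomputed.
LEARNER_CUTOFF_PCT = 35.0


def trim_rt(trials: pd.DataFrame, tail: float = 0.01) -> pd.DataFrame:
    """Remove the fastest and slowest ``tail`` fraction of trials by pooled RT.

    Quantiles are pooled across all participants, sessions and blocks (linear
    interpolation); rows lying exactly on a quantile are retained, and both
    correct and incorrect trials are kept.
    """
    if not 0.0 <= tail < 0.5:
        raise ValueError("tail must lie in [0, 0.5)")
    if len(trials) == 0:
        warnings.warn("trim_rt received an empty table", stacklevel=2)
        return trials.copy()
    if tail == 0.0:
        return trials.copy()
    lo, hi = np.quantile(trials["rt"].to_numpy(), [tail, 1.0 - tail])
    return trials.loc[(trials["rt"] >= lo) & (trials["rt"] <= hi)].copy()


def block_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy (percent) and mean RT per participant x session x block.

    Training blocks ("1".."6") and the generalization block ("G") appear as
    separate rows.
    """
    grp = trials.groupby(["participant_id", "session", "block"], sort=True)
    out = grp.agg(
        n_trials=("correct", "size"),
        accuracy_pct=("correct", lambda c: 100.0 * np.mean(c)),
        mean_rt=("rt", "mean"),
    ).reset_index()
    return out


def classify_learner(final_block_acc_pct: float, cutoff_pct: float = LEARNER_CUTOFF_PCT) -> str:
    """'non_learner' iff final-block (session 3, block 6) accuracy <= cutoff."""
    if final_block_acc_pct is None or np.isnan(final_block_acc_pct):
        raise ValueError("final-block accuracy is missing; participant unclassifiable")
    return "non_learner" if final_block_acc_pct <= cutoff_pct else "learner"


def classify_learners(
    accuracy: pd.DataFrame,
    final_session: int = 3,
    final_block: str = "6",
    cutoff_pct: float = LEARNER_CUTOFF_PCT,
) -> pd.DataFrame:
    """Per-participant learner/non-learner labels from a block-accuracy table.

    Participants without the final training block are flagged unclassifiable
    (label NA).
    """
    final = accuracy[
        (accuracy["session"] == final_session) & (accuracy["block"].astype(str) == final_block)
    ].set_index("participant_id")["accuracy_pct"]
    rows = []
    for pid in accuracy["participant_id"].unique():
        if pid in final.index:
            rows.append((pid, classify_learner(float(final.loc[pid]), cutoff_pct)))
        else:
            rows.append((pid, pd.NA))
    return pd.DataFrame(rows, columns=["participant_id", "learner_class"])


def ospan_score(records) -> int:
    """Operation-span score: the summed length of all perfectly recalled spans.

    A span counts only when the recalled sequence matches the presented one
    exactly and in order; partial recalls contribute 0.  Arithmetic accuracy
    is never used to filter trials.
    """
    total = 0
    for rec in records:
        length = int(rec["span_length"])
        presented = list(rec["presented_letters"])
        recalled = list(rec["recalled_letters"])
        if length != len(presented):
            raise ValueError(
                f"span_length {length} does not match presented sequence {presented!r}"
            )
        if recalled == presented:
            total += length
    return total


def ospan_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant OSPAN scores from a trial-level table."""
    rows = [
        (pid, ospan_score(sub.to_dict("records")))
        for pid, sub in records.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "ospan_score"])


def maintenance_scores(accuracy: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-block accuracy deltas with and without an intersession delay.

    For each participant and session transition (1->2, 2->3):

    * ``no_delay``: block 6 minus block 5 of the earlier session;
    * ``delay``: block 1 of the later session minus block 6 of the earlier
      session (negative values indicate forgetting over the delay).

    Deltas are in percentage points; missing blocks yield missing deltas.
    """
    acc = accuracy.copy()
    acc["block"] = acc["block"].astype(str)
    pivot = acc.pivot_table(
        index="participant_id", columns=["session", "block"], values="accuracy_pct",
        aggfunc="first",
    )

    def get(pid, session, block):
        try:
            return float(pivot.loc[pid, (session, block)])
        except KeyError:
            return np.nan

    rows = []
    for pid in pivot.index:
        for earlier, later in ((1, 2), (2, 3)):
            rows.append(
                {
                    "participant_id": pid,
                    "transition": f"{earlier}to{later}",
                    "delay_type": "no_delay",
                    "delta_pct": get(pid, earlier, "6") - get(pid, earlier, "5"),
                }
            )
            rows.append(
                {
                    "participant_id": pid,
                    "transition": f"{earlier}to{later}",
                    "delay_type": "delay",
                    "delta_pct": get(pid, later, "1") - get(pid, earlier, "6"),
                }
            )
    return pd.DataFrame(rows)


def generalization_score(accuracy: pd.DataFrame) -> pd.DataFrame:
    """Generalization score per participant x session (percentage points).

    Test accuracy on the feedback-free generalization block minus accuracy on
    the final (6th) training block of the same session.
    """
    acc = accuracy.copy()
    acc["block"] = acc["block"].astype(str)
    pivot = acc.pivot_table(
        index=["participant_id", "session"], columns="block", values="accuracy_pct",
        aggfunc="first",
    )
    out = pivot.reset_index()[["participant_id", "session"]].copy()
    gen = pivot[GENERALIZATION_BLOCK] if GENERALIZATION_BLOCK in pivot else np.nan
    blk6 = pivot["6"] if "6" in pivot else np.nan
    out["generalization_score_pct"] = (np.asarray(gen) - np.asarray(blk6))
    return out


def median_split(scores: pd.DataFrame, column: str = "ospan_score") -> pd.DataFrame:
    """High/low WM grouping at the sample median (ties to 'high').

    Used only for visualization-style grouping; association models use the raw
    score.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least two participants")
    med = float(np.median(scores[column].to_numpy()))
    out = scores[["participant_id", column]].copy()
    out["wm_group"] = np.where(out[column] >= med, "high", "low")
    out.attrs["median"] = med
    return out


def metrics_table(
    trials: pd.DataFrame,
    ospan: pd.DataFrame | None = None,
    tail: float = 0.01,
    cutoff_pct: float = LEARNER_CUTOFF_PCT,
) -> dict:
    """End-to-end behavioral scoring: trim, accuracy, classification, scores.

    Returns a dict of tables: ``accuracy`` (per participant x session x
    block), ``participants`` (learner class, OSPAN score, WM group),
    ``maintenance`` and ``generalization``.
    """
    trimmed = trim_rt(trials, tail=tail)
    acc = block_accuracy(trimmed)
    classes = classify_learners(acc, cutoff_pct=cutoff_pct)
    participants = classes
    if ospan is not None:
        scores = ospan if "ospan_score" in ospan.columns else ospan_scores(ospan)
        participants = participants.merge(
            scores[["participant_id", "ospan_score"]], on="participant_id", how="left"
        )
        participants = participants.merge(
            median_split(scores)[["participant_id", "wm_group"]],
            on="participant_id", how="left",
        )
    return {
        "accuracy": acc,
        "participants": participants,
        "maintenance": maintenance_scores(acc),
        "generalization": generalization_score(acc),
    }
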