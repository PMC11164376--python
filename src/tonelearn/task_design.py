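"""Experimental design: stimulus inventory and session/block/trial scaffolding.

The training paradigm is a Mandarin tone category-learning task: four lexical
tone categories (1 high-flat, 2 low-rising, 3 low-dipping, 4 high-falling),
each produced by four native speakers (two female, two male) in five syllable
contexts, giving an 80-item grid (20 per category).  Two speakers (one per
sex) provide the 40 training stimuli; the held-out two provide the 40
generalization stimuli, which are presented without feedback.

Each of three sessions comprises six training blocks of 40 trials (every
training stimulus once per block) followed by one feedback-free
generalization block of 40 trials.  The simulation and the analysis stages
both consume the design objects defined here, so the experiment structure is
encoded exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Syllable contexts in which each tone is produced.
SYLLABLES: tuple[str, ...] = ("bu", "di", "lu", "ma", "mi")

#: Tone category labels (keyboard responses 1-4).
TONE_CATEGORIES: tuple[int, ...] = (1, 2, 3, 4)

#: Speaker sexes; speakers 1-2 are female, 3-4 male by convention.
SPEAKER_SEX: dict[int, str] = {1: "F", 2: "F", 3: "M", 4: "M"}

#: Block label used for the feedback-free generalization block.
GENERALIZATION_BLOCK = "G"


class DesignError(ValueError):
    """Raised when a requested design violates the experiment's structure."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus in the 4 tones x 4 speakers x 5 syllables grid.

    ``duration_ms`` and ``level_db`` record the normalisation applied to the
    natural recordings (440 ms, 70 dB RMS); they are metadata only and enter
    no computation.
    """

    stimulus_id: str
    tone_category: int
    speaker_id: int
    speaker_sex: str
    syllable: str
    role: str  # "training" or "generalization"
    duration_ms: float = 440.0
    level_db: float = 70.0


@dataclass(frozen=True)
class SessionDesign:
    """Session/block/trial structure of the three-session experiment."""

    n_sessions: int = 3
    blocks_per_session: int = 6
    trials_per_block: int = 40
    generalization_trials: int = 40
    chance_probability: float = 0.25
    # Approximate gaps between sessions (days); metadata only.
    intersession_gaps_days: tuple[float, float] = (31.0, 61.0)

    @property
    def trials_per_session(self) -> int:
        """Training plus generalization trials in one session (280)."""
        return self.blocks_per_session * self.trials_per_block + self.generalization_trials

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intersession_gaps_days"] = list(d["intersession_gaps_days"])
        return d


def make_stimulus_grid(training_speakers: Iterable[int] = (1, 3)) -> list[StimulusSpec]:
    """Build the full 80-stimulus grid with a training/generalization split.

    Parameters
    ----------
    training_speakers
        Exactly two speaker ids from {1..4}, one female (1-2) and one male
        (3-4).  Their 40 stimuli are the training set; the remaining two
        speakers' 40 stimuli form the generalization set.

    Returns
    -------
    list of StimulusSpec
        80 stimuli, 20 per tone category, deterministic given the input.
    """
    tset = set(training_speakers)
    if len(tset) != 2 or not tset <= set(SPEAKER_SEX):
        raise DesignError(f"training_speakers must be 2 ids from 1-4, got {sorted(tset)}")
    sexes = {SPEAKER_SEX[s] for s in tset}
    if sexes != {"F", "M"}:
        raise DesignError("training speakers must include one female and one male speaker")

    grid: list[StimulusSpec] = []
    for tone in TONE_CATEGORIES:
        for speaker in sorted(SPEAKER_SEX):
            for syll in SYLLABLES:
                role = "training" if speaker in tset else "generalization"
                grid.append(
                    StimulusSpec(
                        stimulus_id=f"t{tone}_s{speaker}_{syll}",
                        tone_category=tone,
                        speaker_id=speaker,
                        speaker_sex=SPEAKER_SEX[speaker],
                        syllable=syll,
                        role=role,
                    )
                )
    return grid


def make_trial_sequence(
    design: SessionDesign,
    grid: Sequence[StimulusSpec],
    session: int,
    rng_seed: int,
) -> list[tuple[object, StimulusSpec, bool]]:
    """Lay out one session's trials: 6 shuffled training blocks + 1 generalization block.

    Each training block contains every training stimulus exactly once, in a
    uniformly random order drawn from a generator seeded by
    ``(rng_seed, session)``; the generalization block contains every
    generalization stimulus exactly once.  Feedback is given only on training
    trials.

    Returns a list of ``(block, stimulus, feedback_flag)`` where ``block`` is
    1..6 or :data:`GENERALIZATION_BLOCK`.
    """
    training = [s for s in grid if s.role == "training"]
    heldout = [s for s in grid if s.role == "generalization"]
    if len(training) != design.trials_per_block or len(heldout) != design.generalization_trials:
        raise DesignError(
            f"grid has {len(training)} training / {len(heldout)} generalization stimuli; "
            f"design expects {design.trials_per_block} / {design.generalization_trials}"
        )
    rng = np.random.default_rng([rng_seed, session])
    seq: list[tuple[object, StimulusSpec, bool]] = []
    for block in range(1, design.blocks_per_session + 1):
        order = rng.permutation(len(training))
        seq.extend((block, training[j], True) for j in order)
    order = rng.permutation(len(heldout))
    seq.extend((GENERALIZATION_BLOCK, heldout[j], False) for j in order)
    return seq


def grid_to_frame(grid: Sequence[StimulusSpec]) -> pd.DataFrame:
    """Serialize a stimulus grid as a tidy table (one row per stimulus)."""
    return pd.DataFrame([asdict(s) for s in grid])
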