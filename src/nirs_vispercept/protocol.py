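"""Block-design trial schedule of the visual-perception session.

A session is a randomized sequence of trials from a factorial design
(question type x picture saturation x repetition).  Each trial walks through
four fixed-duration stages: problem judgment, picture (diagram) viewing,
question answering, and a fixation/rest interval before the next trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

QUESTIONS: tuple[str, ...] = ("layout", "design", "color", "information")
SATURATIONS: tuple[str, ...] = ("low", "high")
STAGES: tuple[str, ...] = ("judgment", "diagram", "problem", "fixation")
#: 5 optode sites x 3 sub-channels, the fixed montage of the analysis.
CHANNELS: tuple[str, ...] = tuple(f"{site}{sub}" for site in range(1, 6) for sub in "abc")

#: stage durations in seconds; "problem" is the answer stage, whose duration
#: the protocol leaves open — 6 s keeps the nominal session near five minutes.
DEFAULT_STAGE_DURATIONS: Mapping[str, float] = {
    "judgment": 4.0,
    "diagram": 6.0,
    "problem": 6.0,
    "fixation": 8.0,
}


@dataclass(frozen=True)
class Stage:
    name: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Trial:
    index: int
    question: str
    saturation: str
    stages: tuple[Stage, ...]

    @property
    def onset(self) -> float:
        return self.stages[0].onset

    @property
    def end(self) -> float:
        return self.stages[-1].end

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def task_span(self) -> tuple[float, float]:
        """Judgment onset through end of the answer stage (the task window)."""
        return self.stages[0].onset, self.stage("problem").end

    @property
    def fixation_span(self) -> tuple[float, float]:
        fix = self.stage("fixation")
        return fix.onset, fix.end


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered, non-overlapping stage timeline of one session."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        last = -np.inf
        for trial in self.trials:
            names = tuple(s.name for s in trial.stages)
            if names != STAGES:
                raise DataError(f"trial {trial.index}: stage order {names} != {STAGES}")
            for s in trial.stages:
                if s.duration <= 0:
                    raise ConfigurationError(
                        f"trial {trial.index}: non-positive duration for stage {s.name!r}"
                    )
                if s.onset < last:
                    raise DataError(f"trial {trial.index}: overlapping stage {s.name!r}")
                last = s.end

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def end(self) -> float:
        return self.trials[-1].end

    def design_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for t in self.trials:
            key = (t.question, t.saturation)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def validate_full_design(self) -> None:
        """Assert the full factorial session: 16 trials, every cell twice."""
        if len(self.trials) != 16:
            raise DataError(f"expected 16 trials, got {len(self.trials)}")
        counts = self.design_counts()
        for q, s in product(QUESTIONS, SATURATIONS):
            if counts.get((q, s), 0) != 2:
                raise DataError(f"design cell ({q}, {s}) appears {counts.get((q, s), 0)} times")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "onset_s": s.onset,
                "duration_s": s.duration,
                "question": t.question,
                "stage": s.name,
                "saturation": t.saturation,
                "trial_index": t.index,
            }
            for t in self.trials
            for s in t.stages
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSchedule":
        trials = []
        for idx, grp in frame.groupby("trial_index", sort=True):
            grp = grp.sort_values("onset_s")
            stages = tuple(
                Stage(r.stage, float(r.onset_s), float(r.duration_s)) for r in grp.itertuples()
            )
            trials.append(
                Trial(int(idx), grp.question.iloc[0], grp.saturation.iloc[0], stages)
            )
        trials.sort(key=lambda t: t.onset)
        return cls(tuple(trials))

    @classmethod
    def from_tsv(cls, path) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_protocol(config, seed: int | None = None) -> TrialSchedule:
    """Randomized trial schedule for one session.

    The trial order is a seeded shuffle of the factorial design
    (questions x saturations x repeats); stage onsets are laid out
    back-to-back after an initial rest interval.  The same seed always
    produces the identical schedule.
    """
    durations = dict(config.stage_durations)
    for name in STAGES:
        if durations.get(name, 0.0) <= 0:
            raise ConfigurationError(f"stage {name!r} duration must be positive")
    cells = [
        (q, s)
        for q in config.questions
        for s in config.saturations
        for _ in range(config.n_repeats)
    ]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order = rng.permutation(len(cells))

    trials = []
    t = float(config.initial_rest_s)
    for i, cell_idx in enumerate(order):
        q, sat = cells[cell_idx]
        stages = []
        for name in STAGES:
            stages.append(Stage(name, t, durations[name]))
            t += durations[name]
        trials.append(Trial(i, q, sat, tuple(stages)))
    return TrialSchedule(tuple(trials))
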