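"""In-memory containers for recordings, hemoglobin series and windows."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

SIGNALS: tuple[str, ...] = ("hbo2", "hb", "hbt")


@dataclass
class RawIntensityRecording:
    """Two-wavelength light intensities per channel on a uniform grid.

    ``intensity`` has shape (n_channels, n_samples, 2) with the last axis
    ordered like ``wavelengths``.  ``baseline`` holds the per-channel
    baseline intensities (n_channels, 2); when absent, the Beer–Lambert
    inversion estimates it from the start of the session.
    """

    time: np.ndarray
    channels: tuple[str, ...]
    intensity: np.ndarray
    wavelengths: tuple[float, float] = (760.0, 850.0)
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.channels), self.time.size, 2):
            raise DataError(
                f"intensity shape {self.intensity.shape} does not match "
                f"({len(self.channels)}, {self.time.size}, 2)"
            )
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        lo = int(round(self.wavelengths[0]))
        hi = int(round(self.wavelengths[1]))
        n = self.time.size
        return pd.DataFrame(
            {
                "time_s": np.tile(self.time, len(self.channels)),
                "channel": np.repeat(self.channels, n),
                f"intensity_{lo}": self.intensity[:, :, 0].ravel(),
                f"intensity_{hi}": self.intensity[:, :, 1].ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, wavelengths: tuple[float, float] = (760.0, 850.0)
    ) -> "RawIntensityRecording":
        lo = int(round(wavelengths[0]))
        hi = int(round(wavelengths[1]))
        channels = tuple(sorted(frame["channel"].unique()))
        wide_lo = frame.pivot(index="channel", columns="time_s", values=f"intensity_{lo}")
        wide_hi = frame.pivot(index="channel", columns="time_s", values=f"intensity_{hi}")
        wide_lo = wide_lo.loc[list(channels)].sort_index(axis=1)
        wide_hi = wide_hi.loc[list(channels)].sort_index(axis=1)
        time = wide_lo.columns.to_numpy(dtype=float)
        intensity = np.stack([wide_lo.to_numpy(), wide_hi.to_numpy()], axis=-1)
        return cls(time=time, channels=channels, intensity=intensity, wavelengths=wavelengths)

    @classmethod
    def from_csv(cls, path, wavelengths=(760.0, 850.0)) -> "RawIntensityRecording":
        return cls.from_frame(pd.read_csv(path), wavelengths=wavelengths)


@dataclass
class HemoglobinSeries:
    """Relative HbO2/Hb concentration changes per channel; Hbt is their sum."""

    time: np.ndarray
    channels: tuple[str, ...]
    hbo2: np.ndarray
    hb: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        shape = (len(self.channels), self.time.size)
        if self.hbo2.shape != shape or self.hb.shape != shape:
            raise DataError("hbo2/hb arrays must be (n_channels, n_samples)")
        if not (np.isfinite(self.hbo2).all() and np.isfinite(self.hb).all()):
            raise DataError("hemoglobin series contains non-finite values")

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo2 + self.hb

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def get(self, signal: str) -> np.ndarray:
        if signal == "hbo2":
            return self.hbo2
        if signal == "hb":
            return self.hb
        if signal == "hbt":
            return self.hbt
        raise KeyError(signal)

    def to_frame(self) -> pd.DataFrame:
        n = self.time.size
        return pd.DataFrame(
            {
                "time_s": np.tile(self.time, len(self.channels)),
                "channel": np.repeat(self.channels, n),
                "hbo2": self.hbo2.ravel(),
                "hb": self.hb.ravel(),
                "hbt": self.hbt.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HemoglobinSeries":
        channels = tuple(sorted(frame["channel"].unique()))
        hbo2 = frame.pivot(index="channel", columns="time_s", values="hbo2")
        hb = frame.pivot(index="channel", columns="time_s", values="hb")
        hbo2 = hbo2.loc[list(channels)].sort_index(axis=1)
        hb = hb.loc[list(channels)].sort_index(axis=1)
        return cls(
            time=hbo2.columns.to_numpy(dtype=float),
            channels=channels,
            hbo2=hbo2.to_numpy(),
            hb=hb.to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "HemoglobinSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class NormalizedSeries:
    """Min–max normalized signals with the (min, max) provenance per vector.

    ``values[signal]`` is (n_channels, n_samples); ``ranges[signal]`` is
    (n_channels, 2) holding the original (min, max) so the normalization is
    exactly invertible for non-constant vectors.
    """

    time: np.ndarray
    channels: tuple[str, ...]
    values: Mapping[str, np.ndarray]
    ranges: Mapping[str, np.ndarray]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def get(self, signal: str) -> np.ndarray:
        return self.values[signal]

    def denormalize(self, signal: str) -> np.ndarray:
        lo = self.ranges[signal][:, :1]
        hi = self.ranges[signal][:, 1:]
        return self.values[signal] * (hi - lo) + lo


@dataclass
class Window:
    """One labeled analysis window of a participant's session."""

    participant: str
    trial_index: int
    question: str
    stage: str  # per-stage mode: stage name; task_baseline mode: "task" or "baseline"
    saturation: str
    t0: float
    t1: float
    time: np.ndarray
    values: Mapping[str, np.ndarray]  # signal -> (n_channels, n_samples)

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def label(self, classes: int = 16) -> str:
        if classes == 16:
            return f"{self.question}/{self.stage}"
        if classes == 4:
            return self.question
        raise ValueError(f"classes must be 16 or 4, got {classes}")


@dataclass
class WindowSet:
    """Labeled windows of one or more participants' sessions."""

    windows: list[Window]
    channels: tuple[str, ...]
    signals: tuple[str, ...] = SIGNALS
    mode: str = "task_baseline"

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def participants(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(w.participant for w in self.windows))

    def select(
        self,
        question: str | None = None,
        stage: str | None = None,
        participant: str | None = None,
        task_only: bool = False,
    ) -> "WindowSet":
        out = [
            w
            for w in self.windows
            if (question is None or w.question == question)
            and (stage is None or w.stage == stage)
            and (participant is None or w.participant == participant)
            and not (task_only and w.stage in ("baseline", "fixation"))
        ]
        return WindowSet(out, self.channels, self.signals, self.mode)

    def extend(self, other: "WindowSet") -> "WindowSet":
        if other.channels != self.channels or other.mode != self.mode:
            raise DataError("cannot merge window sets with different channels or modes")
        return WindowSet(self.windows + other.windows, self.channels, self.signals, self.mode)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for w in self.windows:
            n = w.time.size
            for sig in self.signals:
                parts.append(
                    pd.DataFrame(
                        {
                            "participant": w.participant,
                            "trial_index": w.trial_index,
                            "label_question": w.question,
                            "label_stage": w.stage,
                            "saturation": w.saturation,
                            "channel": np.repeat(self.channels, n),
                            "signal": sig,
                            "time_s": np.tile(w.time, len(self.channels)),
                            "value": w.values[sig].ravel(),
                        }
                    )
                )
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def concat_window_sets(sets: Iterable[WindowSet]) -> WindowSet:
    sets = list(sets)
    merged = sets[0]
    for other in sets[1:]:
        merged = merged.extend(other)
    return merged
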