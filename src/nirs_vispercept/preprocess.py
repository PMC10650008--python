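"""Band-pass filtering, min–max normalization and protocol-driven windowing."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import (
    SIGNALS,
    HemoglobinSeries,
    NormalizedSeries,
    Window,
    WindowSet,
)
from .errors import ConfigurationError, DataError
from .protocol import TrialSchedule


def bandpass(
    series: HemoglobinSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 2,
) -> HemoglobinSeries:
    """Zero-phase Butterworth band-pass of each channel and signal.

    The filter is applied forward and backward (``sosfiltfilt``) so stage
    labels stay aligned with the filtered response.  Hbt needs no separate
    pass: filtering is linear, so filtered Hbt equals the sum of the
    filtered components.
    """
    nyquist = series.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ConfigurationError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist:g}) Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=series.sampling_rate, output="sos")
    return HemoglobinSeries(
        time=series.time,
        channels=series.channels,
        hbo2=sosfiltfilt(sos, series.hbo2, axis=-1),
        hb=sosfiltfilt(sos, series.hb, axis=-1),
    )


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Map a vector onto [0, 1]: x' = (x - min(x)) / (max(x) - min(x)).

    Constant vectors map to all-zeros with a warning (dead-channel
    robustness) rather than raising.  Returns the normalized vector and the
    original (min, max) so the mapping is exactly invertible.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError("cannot normalize an empty vector")
    if not np.isfinite(x).all():
        raise DataError("cannot normalize a vector with non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant vector normalized to zeros", stacklevel=2)
        return np.zeros_like(x), (lo, hi)
    return (x - lo) / (hi - lo), (lo, hi)


def normalize_series(series: HemoglobinSeries) -> NormalizedSeries:
    """Min–max normalize each channel of each signal over the whole session."""
    values: dict[str, np.ndarray] = {}
    ranges: dict[str, np.ndarray] = {}
    for sig in SIGNALS:
        data = series.get(sig)
        out = np.empty_like(data)
        rng = np.empty((data.shape[0], 2))
        for c in range(data.shape[0]):
            out[c], (rng[c, 0], rng[c, 1]) = minmax_normalize(data[c])
        values[sig] = out
        ranges[sig] = rng
    return NormalizedSeries(
        time=series.time, channels=series.channels, values=values, ranges=ranges
    )


def _slice(time: np.ndarray, t0: float, t1: float) -> slice:
    """Half-open [t0, t1) against the sample grid; each sample in <= 1 window."""
    i0 = int(np.searchsorted(time, t0 - 1e-9, side="left"))
    i1 = int(np.searchsorted(time, t1 - 1e-9, side="left"))
    return slice(i0, i1)


def segment_windows(
    series,
    schedule: TrialSchedule,
    mode: str = "task_baseline",
    participant: str = "p00",
) -> WindowSet:
    """Cut a session into labeled windows following the block design.

    ``task_baseline`` mode emits, per trial, one task window spanning judgment
    through the answer stage (labeled by question) plus one baseline window
    over the fixation interval — 32 windows for a 16-trial session.
    ``per_stage`` mode emits one window per stage, labeled (question, stage)
    — 64 windows for a 16-trial session.

    ``series`` may be a :class:`HemoglobinSeries` or :class:`NormalizedSeries`
    (anything exposing ``time``, ``channels`` and ``get(signal)``).
    """
    if mode not in ("task_baseline", "per_stage"):
        raise ConfigurationError(f"unknown windowing mode {mode!r}")
    t_end = series.time[-1] + 1.0 / series.sampling_rate
    overruns = [t.index for t in schedule.trials if t.end > t_end + 1e-9]
    if overruns:
        raise DataError(f"schedule overruns the recording for trials {overruns}")

    signals = tuple(SIGNALS)
    data = {sig: series.get(sig) for sig in signals}
    windows: list[Window] = []

    def emit(trial, stage_label: str, t0: float, t1: float) -> None:
        sl = _slice(series.time, t0, t1)
        windows.append(
            Window(
                participant=participant,
                trial_index=trial.index,
                question=trial.question,
                stage=stage_label,
                saturation=trial.saturation,
                t0=t0,
                t1=t1,
                time=series.time[sl],
                values={sig: data[sig][:, sl] for sig in signals},
            )
        )

    for trial in schedule.trials:
        if mode == "task_baseline":
            emit(trial, "task", *trial.task_span)
            emit(trial, "baseline", *trial.fixation_span)
        else:
            for stage in trial.stages:
                emit(trial, stage.name, stage.onset, stage.end)
    return WindowSet(windows, tuple(series.channels), signals, mode)
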