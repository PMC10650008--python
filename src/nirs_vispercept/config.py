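"""Configuration objects for simulation and optics.

All physical defaults are configuration, not hard-coded truth: extinction
coefficients, path length and DPF can be overridden for a different device
or wavelength pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .protocol import CHANNELS, DEFAULT_STAGE_DURATIONS, QUESTIONS, SATURATIONS, STAGES

#: Tabulated specific extinction coefficients at 760/850 nm in 1/(mM cm),
#: rows = wavelengths, columns = (HbO2, Hb).  Values are the commonly used
#: literature tabulation for these two wavelengths; override per device.
DEFAULT_EXTINCTION = {
    760.0: {"hbo2": 0.5958, "hb": 1.6745},
    850.0: {"hbo2": 1.1596, "hb": 0.7861},
}


@dataclass(frozen=True)
class MBLLConfig:
    """Optical parameters of the modified Beer–Lambert inversion.

    Concentrations are expressed in µM-equivalent relative units; optical
    density uses base-10 logarithms.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    #: extinction coefficients eps[(wavelength)][chromophore] in 1/(mM cm)
    eps_hbo2: tuple[float, float] = (
        DEFAULT_EXTINCTION[760.0]["hbo2"],
        DEFAULT_EXTINCTION[850.0]["hbo2"],
    )
    eps_hb: tuple[float, float] = (
        DEFAULT_EXTINCTION[760.0]["hb"],
        DEFAULT_EXTINCTION[850.0]["hb"],
    )
    distance_cm: float = 3.0
    dpf: float = 6.0
    #: seconds of session start used to estimate baseline intensity when a
    #: recording carries none explicitly
    baseline_window_s: float = 5.0

    def __post_init__(self) -> None:
        if self.wavelengths[0] == self.wavelengths[1]:
            raise ConfigurationError("the two wavelengths must differ")
        if self.distance_cm <= 0 or self.dpf <= 0:
            raise ConfigurationError("distance and DPF must be positive")
        if abs(self.determinant) < 1e-12:
            raise ConfigurationError("extinction coefficient matrix is singular")

    @property
    def extinction_matrix(self) -> np.ndarray:
        """2x2 matrix, rows = wavelengths, columns = (HbO2, Hb)."""
        return np.array(
            [
                [self.eps_hbo2[0], self.eps_hb[0]],
                [self.eps_hbo2[1], self.eps_hb[1]],
            ]
        )

    @property
    def determinant(self) -> float:
        return (
            self.eps_hbo2[0] * self.eps_hb[1] - self.eps_hbo2[1] * self.eps_hb[0]
        )

    @property
    def pathlength_cm(self) -> float:
        return self.distance_cm * self.dpf


@dataclass(frozen=True)
class SimulationConfig:
    """Forward model of a session: protocol, hemodynamics, noise, scores.

    The defaults encode the study conditions: 29 participants, 16-trial
    sessions (4 questions x 2 saturations x 2 repeats), stage durations
    4/6/6/8 s, 15 channels, 10 Hz sampling, task-evoked HbO2 increases with
    anticorrelated Hb, sinusoidal physiological noise and questionnaire
    scores coupled to the participant's response gain.
    """

    n_participants: int = 29
    sampling_rate: float = 10.0
    stage_durations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DURATIONS)
    )
    questions: tuple[str, ...] = QUESTIONS
    saturations: tuple[str, ...] = SATURATIONS
    n_repeats: int = 2
    channels: tuple[str, ...] = CHANNELS
    initial_rest_s: float = 10.0
    tail_s: float = 10.0

    # canonical double-gamma response
    hrf_peak_time_s: float = 6.0
    hrf_undershoot_time_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0

    #: (question, stage) -> per-channel HbO2 amplitude pattern (µM-equivalent);
    #: None builds positive task-stage patterns from the seed substream.
    class_amplitudes: Mapping[tuple[str, str], np.ndarray] | None = None
    #: SD of the between-participant multiplicative response gain around 1
    amplitude_scale_sd: float = 0.2
    hb_ratio: float = 0.3

    white_sd: float = 0.1
    cardiac_amp: float = 0.05
    cardiac_hz: float = 1.0
    resp_amp: float = 0.05
    resp_hz: float = 0.3
    mayer_amp: float = 0.05
    mayer_hz: float = 0.1
    drift_slope: float = 0.0005  # µM-equivalent per second

    score_baseline: float = 5.0
    score_coupling: float = 1.0
    score_noise_sd: float = 0.1

    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        for name, amp in (
            ("white_sd", self.white_sd),
            ("cardiac_amp", self.cardiac_amp),
            ("resp_amp", self.resp_amp),
            ("mayer_amp", self.mayer_amp),
        ):
            if amp < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in STAGES:
            if self.stage_durations.get(name, 0.0) <= 0:
                raise ConfigurationError(f"stage {name!r} duration must be positive")
        if not np.isfinite(self.score_coupling):
            raise ConfigurationError("score_coupling must be finite")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def is_full_design(self) -> bool:
        return (
            tuple(self.questions) == QUESTIONS
            and tuple(self.saturations) == SATURATIONS
            and self.n_repeats == 2
        )


def config_from_mapping(cls, mapping: Mapping) -> object:
    """Build a config dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("wavelengths", "eps_hbo2", "eps_hb", "questions", "saturations", "channels"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)
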