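"""Forward simulation of sessions: hemodynamics, optics and questionnaire scores.

The generator emulates the statistical structure the analysis assumes:
block-design trials whose stages evoke a canonical double-gamma hemodynamic
response in HbO2 with an anticorrelated Hb response, superimposed on white
noise, sinusoidal physiological rhythms (cardiac ~1 Hz, respiratory ~0.3 Hz,
Mayer waves ~0.1 Hz) and a slow linear drift.  Questionnaire scores are
linearly coupled to each participant's response gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .config import MBLLConfig, SimulationConfig
from .containers import HemoglobinSeries, RawIntensityRecording
from .errors import ConfigurationError
from .mbll import total_hemoglobin  # noqa: F401  (re-exported convenience)
from .protocol import STAGES, TrialSchedule, build_protocol


def hrf_kernel(
    t: np.ndarray,
    peak_time_s: float = 6.0,
    undershoot_time_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``t`` (s), peak normalized to 1.

    Each gamma has unit scale, so its mode equals shape - 1; the shapes are
    chosen so the positive lobe peaks at ``peak_time_s`` and the undershoot
    at ``undershoot_time_s``.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, a=peak_time_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, a=undershoot_time_s + 1.0
    )
    h[t < 0] = 0.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def default_class_patterns(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str], np.ndarray]:
    """Positive per-channel amplitude patterns for every task stage.

    Amplitudes are drawn once per (question, stage) in [0.7, 1.3] so every
    class is distinct but all responses are activations (HbO2 up, Hb down);
    the fixation stage evokes no response.
    """
    n = len(config.channels)
    patterns: dict[tuple[str, str], np.ndarray] = {}
    for q in config.questions:
        for stage in STAGES:
            if stage == "fixation":
                patterns[(q, stage)] = np.zeros(n)
            else:
                patterns[(q, stage)] = 0.7 + 0.6 * rng.random(n)
    return patterns


def random_class_patterns(
    seed: int,
    questions: tuple[str, ...],
    stages: tuple[str, ...] = STAGES,
    n_channels: int = 15,
    scale: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Distinct standard-normal per-channel patterns for every (question, stage)."""
    rng = np.random.default_rng(seed)
    return {
        (q, st): scale * rng.standard_normal(n_channels) for q in questions for st in stages
    }


def _physio_noise(
    rng: np.random.Generator, t: np.ndarray, config: SimulationConfig, amp_factor: float = 1.0
) -> np.ndarray:
    n_ch = len(config.channels)
    noise = rng.normal(0.0, config.white_sd * amp_factor, size=(n_ch, t.size))
    for amp, freq in (
        (config.cardiac_amp, config.cardiac_hz),
        (config.resp_amp, config.resp_hz),
        (config.mayer_amp, config.mayer_hz),
    ):
        if amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, 1))
            noise += amp * amp_factor * np.sin(2.0 * np.pi * freq * t[None, :] + phase)
    if config.drift_slope != 0.0:
        slope = config.drift_slope * amp_factor * rng.choice([-1.0, 1.0], size=(n_ch, 1))
        noise += slope * (t[None, :] - t.mean())
    return noise


def simulate_hemodynamics(
    schedule: TrialSchedule,
    config: SimulationConfig,
    seed: int | None = None,
    amplitude_scale: float = 1.0,
) -> HemoglobinSeries:
    """Simulate one session's HbO2/Hb series on the schedule's timeline.

    Each stage contributes ``amplitude * HRF(t - onset)`` per channel (an
    event-related impulse response at the stage onset, peak equal to the
    amplitude); dHb is ``-hb_ratio`` times the clean dHbO2 plus independent
    noise.  The series is fully determined by config + seed.
    """
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round((schedule.end + config.tail_s) * fs)) + 1
    t = np.arange(n) * dt

    entropy = config.seed if seed is None else seed
    ss = entropy if isinstance(entropy, np.random.SeedSequence) else np.random.SeedSequence(entropy)
    rng_pat, rng_noise_o2, rng_noise_hb = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    patterns = config.class_amplitudes
    if patterns is None:
        patterns = default_class_patterns(config, rng_pat)

    kernel = hrf_kernel(
        np.arange(0.0, 32.0, dt),
        config.hrf_peak_time_s,
        config.hrf_undershoot_time_s,
        config.hrf_undershoot_ratio,
    )
    n_ch = len(config.channels)
    clean = np.zeros((n_ch, n))
    for trial in schedule.trials:
        for stage in trial.stages:
            amp = patterns.get((trial.question, stage.name))
            if amp is None or not np.any(amp):
                continue
            amp = np.asarray(amp, dtype=float)
            i0 = int(round(stage.onset * fs))
            i1 = min(i0 + kernel.size, n)
            if i0 >= n:
                continue
            clean[:, i0:i1] += amp[:, None] * kernel[None, : i1 - i0]
    clean *= amplitude_scale

    hbo2 = clean + _physio_noise(rng_noise_o2, t, config)
    hb = -config.hb_ratio * clean + _physio_noise(
        rng_noise_hb, t, config, amp_factor=config.hb_ratio
    )
    return HemoglobinSeries(time=t, channels=tuple(config.channels), hbo2=hbo2, hb=hb)


def forward_intensities(
    series: HemoglobinSeries,
    optics: MBLLConfig,
    baseline_intensity: float = 1.0,
) -> RawIntensityRecording:
    """Emit raw intensities whose Beer–Lambert inversion reproduces ``series``.

    The emitted recording carries the baseline intensities explicitly, making
    ``invert_mbll(forward_intensities(x)) == x`` an exact round trip.
    """
    if baseline_intensity <= 0:
        raise ConfigurationError("baseline intensity must be positive")
    eps = optics.extinction_matrix  # rows wavelengths, cols (HbO2, Hb)
    conc_mM = np.stack([series.hbo2, series.hb], axis=-1) / 1e3  # (C, n, 2)
    dod = conc_mM @ eps.T * optics.pathlength_cm  # (C, n, 2)
    intensity = baseline_intensity * 10.0 ** (-dod)
    baseline = np.full((len(series.channels), 2), float(baseline_intensity))
    return RawIntensityRecording(
        time=series.time,
        channels=series.channels,
        intensity=intensity,
        wavelengths=optics.wavelengths,
        baseline=baseline,
    )


def simulate_scores(
    schedule: TrialSchedule,
    config: SimulationConfig,
    seed: int | None = None,
    amplitude_scale: float = 1.0,
) -> dict[str, float]:
    """Per-question questionnaire scores for one participant.

    score = baseline + coupling * amplitude_scale + noise, so with positive
    coupling higher-responding participants score higher in expectation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    questions = tuple(dict.fromkeys(t.question for t in schedule.trials))
    return {
        q: float(
            config.score_baseline
            + config.score_coupling * amplitude_scale
            + rng.normal(0.0, config.score_noise_sd)
        )
        for q in questions
    }


@dataclass
class ParticipantData:
    participant: str
    schedule: TrialSchedule
    hemoglobin: HemoglobinSeries
    scores: dict[str, float]
    amplitude_scale: float
    recording: RawIntensityRecording | None = None


@dataclass
class Study:
    participants: list[ParticipantData]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.participants)

    def scores_frame(self) -> pd.DataFrame:
        rows = [
            {"participant": p.participant, "question": q, "score": s}
            for p in self.participants
            for q, s in p.scores.items()
        ]
        return pd.DataFrame(rows)


def simulate_study(
    config: SimulationConfig,
    seed: int | None = None,
    amplitude_scales: np.ndarray | None = None,
    optics: MBLLConfig | None = None,
) -> Study:
    """Simulate a cohort: one schedule, series and score set per participant.

    ``amplitude_scales`` overrides the per-participant response gains (length
    ``n_participants``); by default gains are drawn around 1 with SD
    ``amplitude_scale_sd``, floored at 0.1.  When ``optics`` is given each
    participant also carries the forward-modeled raw intensity recording.
    """
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    # substreams: class patterns, gains, then one per participant
    pattern_seed, gain_seed, *part_seeds = master.spawn(config.n_participants + 2)
    if config.class_amplitudes is None:
        # class patterns are a study-level property shared by all participants;
        # between-participant variation enters only through the gain
        config = config.replace(
            class_amplitudes=default_class_patterns(config, np.random.default_rng(pattern_seed))
        )
    if amplitude_scales is None:
        gain_rng = np.random.default_rng(gain_seed)
        amplitude_scales = np.maximum(
            0.1, 1.0 + config.amplitude_scale_sd * gain_rng.standard_normal(config.n_participants)
        )
    amplitude_scales = np.asarray(amplitude_scales, dtype=float)
    if amplitude_scales.size != config.n_participants:
        raise ConfigurationError("amplitude_scales length must equal n_participants")

    participants = []
    for i, pseed in enumerate(part_seeds):
        sched_seed, hemo_seed, score_seed = pseed.spawn(3)
        schedule = build_protocol(config, seed=sched_seed)
        hemo = simulate_hemodynamics(
            schedule, config, seed=hemo_seed, amplitude_scale=amplitude_scales[i]
        )
        scores = simulate_scores(
            schedule, config, seed=score_seed, amplitude_scale=amplitude_scales[i]
        )
        rec = forward_intensities(hemo, optics) if optics is not None else None
        participants.append(
            ParticipantData(
                participant=f"p{i:02d}",
                schedule=schedule,
                hemoglobin=hemo,
                scores=scores,
                amplitude_scale=float(amplitude_scales[i]),
                recording=rec,
            )
        )
    return Study(participants=participants, config=config)
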