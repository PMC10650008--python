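"""Forward simulation: hemodynamics, optics round trip, score coupling."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import nirs_vispercept as nv
from nirs_vispercept.protocol import STAGES
from nirs_vispercept.simulate import default_class_patterns, hrf_kernel


def _quiet_config(**kwargs):
    base = dict(
        white_sd=0.0,
        cardiac_amp=0.0,
        resp_amp=0.0,
        mayer_amp=0.0,
        drift_slope=0.0,
        seed=5,
    )
    base.update(kwargs)
    return nv.SimulationConfig(**base)


def _zero_amplitudes(cfg):
    return {
        (q, st): np.zeros(len(cfg.channels)) for q in cfg.questions for st in STAGES
    }


def test_null_model_is_identically_zero(schedule):
    cfg = _quiet_config()
    cfg = cfg.replace(class_amplitudes=_zero_amplitudes(cfg))
    hemo = nv.simulate_hemodynamics(schedule, cfg, seed=5)
    assert np.all(hemo.hbo2 == 0.0)
    assert np.all(hemo.hb == 0.0)


def test_single_stage_peak_matches_convolution_oracle(sim_config):
    """One stage with amplitude A on one channel, no noise: the peak equals A
    at onset + HRF peak time, and the whole trace equals the discrete
    convolution of the onset impulse train with the HRF kernel."""
    amp = 2.5
    cfg = _quiet_config(saturations=("low",), n_repeats=1)
    patterns = _zero_amplitudes(cfg)
    patterns[("layout", "judgment")] = np.array([amp] + [0.0] * 14)
    cfg = cfg.replace(class_amplitudes=patterns)
    schedule = nv.build_protocol(cfg, seed=1)
    hemo = nv.simulate_hemodynamics(schedule, cfg, seed=5)

    trial = next(t for t in schedule.trials if t.question == "layout")
    onset = trial.stage("judgment").onset
    fs = cfg.sampling_rate
    peak_idx = int(np.argmax(hemo.hbo2[0]))
    assert hemo.hbo2[0, peak_idx] == pytest.approx(amp, rel=1e-9)
    assert hemo.time[peak_idx] == pytest.approx(onset + cfg.hrf_peak_time_s, abs=1 / fs)

    # oracle: convolve an impulse at the onset sample with the kernel
    impulses = np.zeros(hemo.time.size)
    impulses[int(round(onset * fs))] = amp
    kernel = hrf_kernel(np.arange(0.0, 32.0, 1 / fs))
    oracle = np.convolve(impulses, kernel)[: hemo.time.size]
    np.testing.assert_allclose(hemo.hbo2[0], oracle, atol=1e-12)
    # anticorrelated deoxygenated response
    np.testing.assert_allclose(hemo.hb[0], -cfg.hb_ratio * oracle, atol=1e-12)


def test_hbt_is_elementwise_sum(hemoglobin):
    np.testing.assert_allclose(hemoglobin.hbt, hemoglobin.hbo2 + hemoglobin.hb, atol=0)


def test_simulation_deterministic_under_seed(schedule, sim_config):
    a = nv.simulate_hemodynamics(schedule, sim_config, seed=11)
    b = nv.simulate_hemodynamics(schedule, sim_config, seed=11)
    assert np.array_equal(a.hbo2, b.hbo2) and np.array_equal(a.hb, b.hb)


def test_cardiac_noise_dominates_spectrum_at_configured_frequency(schedule):
    cfg = _quiet_config(cardiac_amp=0.5, cardiac_hz=1.1)
    cfg = cfg.replace(class_amplitudes=_zero_amplitudes(cfg))
    hemo = nv.simulate_hemodynamics(schedule, cfg, seed=2)
    x = hemo.hbo2[0]
    freqs = np.fft.rfftfreq(x.size, d=1 / cfg.sampling_rate)
    power = np.abs(np.fft.rfft(x)) ** 2
    power[freqs < 0.02] = 0.0  # ignore DC leakage
    assert abs(freqs[np.argmax(power)] - 1.1) <= 0.1


def test_forward_intensities_zero_change_gives_baseline(hemoglobin, optics):
    zero = nv.HemoglobinSeries(
        time=hemoglobin.time,
        channels=hemoglobin.channels,
        hbo2=np.zeros_like(hemoglobin.hbo2),
        hb=np.zeros_like(hemoglobin.hb),
    )
    rec = nv.forward_intensities(zero, optics, baseline_intensity=0.8)
    assert np.all(rec.intensity == 0.8)


def test_forward_log_ratio_matches_hand_solved_system(optics):
    """For one sample (dHbO2, dHb) = (1.0, -0.3) µM the emitted log-ratios
    equal the hand-multiplied extinction system."""
    t = np.array([0.0, 1.0])
    series = nv.HemoglobinSeries(
        time=t,
        channels=("1a",),
        hbo2=np.array([[0.0, 1.0]]),
        hb=np.array([[0.0, -0.3]]),
    )
    rec = nv.forward_intensities(series, optics)
    log_ratios = np.log10(rec.baseline[0] / rec.intensity[0, 1])
    c = np.array([1.0, -0.3]) / 1e3  # mM
    expected = optics.extinction_matrix @ c * optics.pathlength_cm
    np.testing.assert_allclose(log_ratios, expected, rtol=1e-12)


def test_scores_track_amplitude_order_without_noise(schedule):
    cfg = _quiet_config(score_coupling=10.0, score_noise_sd=0.0)
    scales = [0.5, 1.0, 1.5, 2.0]
    scores = [
        nv.simulate_scores(schedule, cfg, seed=9, amplitude_scale=s)["layout"] for s in scales
    ]
    assert scores == sorted(scores)


def test_scores_uncorrelated_under_null_coupling(schedule):
    cfg = _quiet_config(score_coupling=0.0, score_noise_sd=1.0)
    rng = np.random.default_rng(0)
    scales = rng.uniform(0.5, 2.0, size=200)
    scores = [
        nv.simulate_scores(schedule, cfg, seed=int(i), amplitude_scale=s)["layout"]
        for i, s in enumerate(scales)
    ]
    rho = spearmanr(scales, scores).statistic
    assert abs(rho) < 0.15


def test_score_coupling_yields_high_rank_correlation(schedule):
    """coupling 1, noise SD 0.1, 100 participants: Spearman rho > 0.9,
    cross-checked against a brute-force rank correlation."""
    cfg = _quiet_config(score_coupling=1.0, score_noise_sd=0.1)
    rng = np.random.default_rng(1)
    scales = rng.uniform(0.5, 1.5, size=100)
    scores = np.array(
        [
            nv.simulate_scores(schedule, cfg, seed=int(i), amplitude_scale=s)["layout"]
            for i, s in enumerate(scales)
        ]
    )
    rho = spearmanr(scales, scores).statistic
    assert rho > 0.9
    # brute-force oracle: Pearson correlation of the rank vectors
    def ranks(v):
        return np.argsort(np.argsort(v)).astype(float)

    ra, rb = ranks(scales), ranks(scores)
    oracle = np.corrcoef(ra, rb)[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_study_level_patterns_shared_across_participants():
    cfg = nv.SimulationConfig(n_participants=2, amplitude_scale_sd=0.0, seed=4)
    study = nv.simulate_study(cfg)
    assert len(study) == 2
    # same seed reproduces the study bit-identically
    again = nv.simulate_study(cfg)
    for p, q in zip(study.participants, again.participants):
        assert np.array_equal(p.hemoglobin.hbo2, q.hemoglobin.hbo2)
        assert p.scores == q.scores


def test_default_patterns_silent_during_fixation(sim_config, rng):
    patterns = default_class_patterns(sim_config, rng)
    for q in sim_config.questions:
        assert np.all(patterns[(q, "fixation")] == 0.0)
        assert np.all(patterns[(q, "judgment")] > 0.0)
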