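"""High/low score-group splitting and Welch comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nirs_vispercept as nv
from nirs_vispercept.errors import DataError


def _scores(values, question="layout"):
    return pd.DataFrame(
        {
            "participant": [f"p{i}" for i in range(len(values))],
            "question": question,
            "score": values,
        }
    )


def test_mean_split_assigns_groups():
    grouping = nv.split_scores(_scores([1.0, 2.0, 3.0, 4.0]), "layout")
    assert grouping == {"p0": "low", "p1": "low", "p2": "high", "p3": "high"}


def test_degenerate_split_raises():
    with pytest.raises(DataError, match="degenerate"):
        nv.split_scores(_scores([5.0, 5.0, 5.0]), "layout")
    with pytest.raises(DataError):
        nv.split_scores(_scores([1.0]), "layout")


def test_skewed_split_follows_the_mean():
    grouping = nv.split_scores(_scores([1.0, 1.0, 10.0]), "layout")
    assert grouping == {"p0": "low", "p1": "low", "p2": "high"}


def _means_frame(high_vals, low_vals):
    """Participant-means frame with one (signal, channel) column."""
    idx = [f"h{i}" for i in range(len(high_vals))] + [f"l{i}" for i in range(len(low_vals))]
    frame = pd.DataFrame({("hbo2", "1a"): list(high_vals) + list(low_vals)}, index=idx)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["signal", "channel"])
    grouping = {**{f"h{i}": "high" for i in range(len(high_vals))},
                **{f"l{i}": "low" for i in range(len(low_vals))}}
    return frame, grouping


def test_identical_group_populations_give_null_result():
    vals = [0.1, 0.4, 0.7, 1.0]
    frame, grouping = _means_frame(vals, vals)
    table = nv.welch_table(frame, grouping)
    assert table.loc[0, "mean_high"] == pytest.approx(table.loc[0, "mean_low"])
    assert table.loc[0, "p_value"] == pytest.approx(1.0)


def test_group_means_match_direct_averages_and_scipy():
    high, low = [1.0, 1.2, 1.4], [0.5, 0.6, 0.8]
    frame, grouping = _means_frame(high, low)
    table = nv.welch_table(frame, grouping)
    assert table.loc[0, "mean_high"] == pytest.approx(sum(high) / 3)
    assert table.loc[0, "mean_low"] == pytest.approx(sum(low) / 3)
    oracle = stats.ttest_ind(high, low, equal_var=False).pvalue
    assert table.loc[0, "p_value"] == pytest.approx(oracle, rel=1e-12)


def test_swapping_group_labels_preserves_p_and_swaps_means():
    frame, grouping = _means_frame([1.0, 1.2, 1.4], [0.5, 0.6, 0.8])
    swapped = {p: ("high" if g == "low" else "low") for p, g in grouping.items()}
    a = nv.welch_table(frame, grouping)
    b = nv.welch_table(frame, swapped)
    assert a.loc[0, "p_value"] == pytest.approx(b.loc[0, "p_value"])
    assert a.loc[0, "mean_high"] == pytest.approx(b.loc[0, "mean_low"])


def test_group_too_small_rejected():
    frame, grouping = _means_frame([1.0], [0.5, 0.6])
    with pytest.raises(DataError):
        nv.welch_table(frame, grouping)


def test_type_i_error_calibrated_under_null():
    """Null coupling: the fraction of p < 0.05 over many simulated
    participant-mean datasets is ~5% (binomial tolerance)."""
    rng = np.random.default_rng(0)
    rejections, total = 0, 0
    for _ in range(250):
        vals = rng.normal(size=12)
        frame, grouping = _means_frame(vals[:6], vals[6:])
        p = nv.welch_table(frame, grouping).loc[0, "p_value"]
        rejections += p < 0.05
        total += 1
    rate = rejections / total
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total) + 0.005


def test_power_monotone_in_amplitude_gap():
    gaps = [0.0, 0.5, 1.0, 2.0]
    med_logp = []
    for gap in gaps:
        ps = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            low = rng.normal(size=8)
            high = rng.normal(loc=gap, size=8)
            frame, grouping = _means_frame(high, low)
            ps.append(nv.welch_table(frame, grouping).loc[0, "p_value"])
        med_logp.append(np.median(-np.log10(ps)))
    assert all(a <= b + 1e-9 for a, b in zip(med_logp, med_logp[1:]))


def test_fdr_and_mannwhitney_options():
    rng = np.random.default_rng(3)
    idx = [f"p{i}" for i in range(10)]
    cols = pd.MultiIndex.from_tuples(
        [("hbo2", "1a"), ("hb", "2b")], names=["signal", "channel"]
    )
    frame = pd.DataFrame(rng.normal(size=(10, 2)), index=idx, columns=cols)
    grouping = {p: ("high" if i < 5 else "low") for i, p in enumerate(idx)}
    table = nv.welch_table(frame, grouping, test="mannwhitney", fdr=True)
    assert "p_adj" in table.columns
    assert np.all(table["p_adj"] >= table["p_value"] - 1e-12)


def test_group_difference_recovers_simulated_amplitude_gap(optics):
    """End to end on a small cohort with a 1.5x response gap: group means
    differ in the right direction and match a direct re-averaging."""
    scales = np.array([1.0] * 5 + [1.5] * 5)
    cfg = nv.SimulationConfig(n_participants=10, white_sd=0.05, seed=21)
    study = nv.simulate_study(cfg, amplitude_scales=scales, optics=optics)
    sets = []
    for p in study.participants:
        filt = nv.bandpass(nv.invert_mbll(p.recording, optics))
        sets.append(nv.segment_windows(filt, p.schedule, mode="task_baseline", participant=p.participant))
    windows = nv.concat_window_sets(sets)
    grouping = nv.split_scores(study.scores_frame(), "layout")
    table = nv.group_difference(windows, grouping, "layout")
    # activation raises HbO2/Hbt and lowers Hb, so the gap flips sign for Hb
    gap = table["mean_high"] - table["mean_low"]
    assert np.all(gap[table["signal"] != "hb"] > 0)
    assert np.all(gap[table["signal"] == "hb"] < 0)
    assert table["n_high"].iloc[0] == 5 and table["n_low"].iloc[0] == 5
    # independent recomputation of one cell's group mean
    means = nv.participant_task_means(windows, "layout")
    high = [p.participant for p in study.participants if grouping[p.participant] == "high"]
    cell = table[(table.signal == "hbo2") & (table.channel == "1a")].iloc[0]
    assert cell["mean_high"] == pytest.approx(means.loc[high, ("hbo2", "1a")].mean())


def test_group_curves_shape(optics):
    scales = np.array([1.0, 1.0, 1.5, 1.5])
    cfg = nv.SimulationConfig(n_participants=4, white_sd=0.05, seed=22)
    study = nv.simulate_study(cfg, amplitude_scales=scales, optics=optics)
    sets = [
        nv.segment_windows(
            nv.bandpass(p.hemoglobin), p.schedule, mode="task_baseline", participant=p.participant
        )
        for p in study.participants
    ]
    windows = nv.concat_window_sets(sets)
    grouping = {"p00": "low", "p01": "low", "p02": "high", "p03": "high"}
    curves = nv.group_curves(windows, grouping, "layout")
    assert set(curves["group"]) == {"high", "low"}
    assert curves["value"].between(0.0, 1.0).all()
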