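"""Mutual-information estimation and channel retention."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

import nirs_vispercept as nv
from nirs_vispercept.channel_screen import (
    JointHistogram,
    channel_scores,
    pooled_retention,
    quantile_bin,
)
from nirs_vispercept.errors import ConfigurationError, DataError


def test_joint_histogram_perfect_pairing():
    h = nv.joint_histogram(np.array([0.0, 1.0]), np.array([0.0, 1.0]), n_bins=2)
    np.testing.assert_array_equal(h.joint, [[1, 0], [0, 1]])


def test_joint_histogram_conserves_count_and_marginals(rng):
    x, y = rng.uniform(size=(2, 500))
    h = nv.joint_histogram(x, y, n_bins=10)
    assert h.n == 500
    np.testing.assert_array_equal(h.marginal_x, h.joint.sum(axis=1))
    np.testing.assert_array_equal(h.marginal_y, h.joint.sum(axis=0))


def test_joint_histogram_matches_nested_loop_oracle(rng):
    x, y = rng.uniform(size=(2, 1000))
    n_bins = 10
    h = nv.joint_histogram(x, y, n_bins=n_bins)
    oracle = np.zeros((n_bins, n_bins))
    for xi, yi in zip(x, y):
        i = min(int((xi - x.min()) / (x.max() - x.min()) * n_bins), n_bins - 1)
        j = min(int((yi - y.min()) / (y.max() - y.min()) * n_bins), n_bins - 1)
        oracle[i, j] += 1
    np.testing.assert_array_equal(h.joint, oracle)


def test_length_mismatch_rejected():
    with pytest.raises(DataError):
        nv.joint_histogram(np.zeros(3), np.zeros(4))


def test_self_information_of_uniform_four_bins_is_two_bits():
    x = np.repeat([0.0, 1.0, 2.0, 3.0], 25)
    h = nv.joint_histogram(x, x, n_bins=4)
    assert nv.mutual_information(h) == pytest.approx(2.0, abs=1e-12)


def test_factorized_joint_table_has_zero_mutual_information():
    joint = np.outer([10, 30], [20, 40]) / 10.0
    h = JointHistogram(x_edges=np.arange(3.0), y_edges=np.arange(3.0), joint=joint)
    assert nv.mutual_information(h) == pytest.approx(0.0, abs=1e-12)


def test_hand_evaluated_two_by_two_table():
    h = JointHistogram(
        x_edges=np.arange(3.0),
        y_edges=np.arange(3.0),
        joint=np.array([[2.0, 1.0], [1.0, 2.0]]),
    )
    # direct summation over the four cells
    expected = 2 * (2 / 6) * np.log2((2 / 6) / 0.25) + 2 * (1 / 6) * np.log2((1 / 6) / 0.25)
    assert nv.mutual_information(h) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.0817, abs=5e-5)


def test_plugin_estimate_agrees_with_sklearn_on_binned_labels(rng):
    """Independent cross-check: sklearn's mutual_info_score on the bin labels
    (nats) must equal our plug-in estimate (bits) up to the log base."""
    x, y = rng.normal(size=(2, 2000))
    y = y + 0.8 * x
    ours = nv.mutual_information(nv.joint_histogram(x, y, n_bins=8))
    xb = np.clip(((x - x.min()) / (x.max() - x.min()) * 8).astype(int), 0, 7)
    yb = np.clip(((y - y.min()) / (y.max() - y.min()) * 8).astype(int), 0, 7)
    theirs = mutual_info_score(xb, yb) / np.log(2)
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_mi_matrix_symmetric_with_dominant_diagonal(per_stage_windows):
    m = nv.mi_matrix(per_stage_windows, "layout", "hbo2")
    vals = m.to_numpy()
    np.testing.assert_array_equal(vals, vals.T)
    assert np.all(vals >= 0)
    assert np.all(np.diag(vals)[:, None] >= vals - 1e-9)


def test_duplicated_channel_reaches_self_information(per_stage_windows):
    m = nv.mi_matrix(per_stage_windows, "layout", "hbo2")
    # duplicating a channel under a new label is equivalent to comparing a
    # channel with itself: off-diagonal MI equals the diagonal self-MI
    assert m.loc["1a", "1a"] == pytest.approx(
        nv.mutual_information(
            nv.joint_histogram(
                *(2 * [np.concatenate([w.values["hbo2"][0] for w in per_stage_windows.select(question="layout", task_only=True)])]),
            )
        ),
        abs=1e-9,
    )


def test_independent_noise_mi_within_bias_bound(rng):
    """Plug-in MI of independent channels stays below ~3x the analytic
    (n_bins-1)^2 / (2 N ln 2) bias of the estimator."""
    n, n_bins = 10_000, 10
    x, y = rng.normal(size=(2, n))
    mi = nv.mutual_information(nv.joint_histogram(x, y, n_bins=n_bins))
    assert mi < 3 * (n_bins - 1) ** 2 / (2 * n * np.log(2))


def _toy_matrix():
    m = pd.DataFrame(
        [[1.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 1.0]],
        index=["A", "B", "C"],
        columns=["A", "B", "C"],
    )
    return m


def test_retention_scores_and_topk_match_brute_force():
    m = _toy_matrix()
    scores = channel_scores(m)
    assert scores["A"] == pytest.approx(0.30)
    assert scores["B"] == pytest.approx(0.40)
    assert scores["C"] == pytest.approx(0.20)
    assert nv.retain_channels(m, k=2) == ["A", "B"]
    assert nv.retain_channels(m, k=3) == ["A", "B", "C"]


def test_retention_count_and_range_checks(per_stage_windows):
    m = nv.mi_matrix(per_stage_windows, "design", "hb")
    assert len(nv.retain_channels(m, k=7)) == 7
    assert nv.retain_channels(m, k=15) == sorted(m.index)
    with pytest.raises(ConfigurationError):
        nv.retain_channels(m, k=0)


def test_retention_invariant_to_channel_order():
    m = _toy_matrix()
    perm = ["C", "A", "B"]
    assert nv.retain_channels(m.loc[perm, perm], k=2) == nv.retain_channels(m, k=2)


def test_threshold_mode_retains_above_cutoff():
    m = _toy_matrix()
    assert nv.retain_channels(m, mode="threshold", threshold=0.25) == ["A", "B"]


def test_common_channels_intersection():
    sel = nv.ChannelSelection(
        retained={
            ("layout", "hb"): ["1b", "2b", "3a"],
            ("layout", "hbo2"): ["1b", "1c", "2b"],
            ("layout", "hbt"): ["1b", "2b", "4a"],
        }
    )
    assert sel.common("layout") == ["1b", "2b"]
    assert nv.common_channels(sel) == {"layout": ["1b", "2b"]}
    sel2 = nv.ChannelSelection(
        retained={
            ("color", "hb"): ["1a"],
            ("color", "hbo2"): ["2a"],
            ("color", "hbt"): ["3a"],
        }
    )
    assert sel2.common("color") == []
    with pytest.raises(DataError):
        nv.ChannelSelection(retained={("design", "hb"): ["1a"]}).common("design")


def test_noise_does_not_inflate_mi_in_expectation(rng):
    """Adding independent noise to one channel does not raise its estimated
    MI with another, on average over many seeds."""
    deltas = []
    for i in range(50):
        r = np.random.default_rng(i)
        x = r.normal(size=800)
        y = x + r.normal(size=800)
        noisy = x + r.normal(scale=1.0, size=800)
        base = nv.mutual_information(nv.joint_histogram(x, y, 8))
        degraded = nv.mutual_information(nv.joint_histogram(noisy, y, 8))
        deltas.append(degraded - base)
    assert np.mean(deltas) < 0


def test_quantile_binned_mi_invariant_to_monotone_transform(rng):
    x, y = rng.normal(size=(2, 1000))
    y = y + x
    a = nv.mi_matrix  # noqa: F841  (surface sanity)
    base = nv.mutual_information(
        nv.joint_histogram(quantile_bin(x, 8).astype(float), quantile_bin(y, 8).astype(float), 8)
    )
    warped = nv.mutual_information(
        nv.joint_histogram(
            quantile_bin(np.exp(x), 8).astype(float), quantile_bin(y, 8).astype(float), 8
        )
    )
    assert warped == pytest.approx(base, abs=1e-12)


def test_pooled_retention_averages_matrices():
    m1 = _toy_matrix()
    m2 = _toy_matrix() * 0.0
    assert pooled_retention([m1, m2], k=2) == nv.retain_channels(m1, k=2)
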