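"""Mutual-information channel screening.

Pairwise mutual information between channels is estimated with the plug-in
(histogram) estimator in bits.  Each channel is scored by its mean
off-diagonal MI with all other channels, and the top-k (default 7) channels
are retained per (question, signal); the per-question "common" channels are
the intersection of the three signals' retained sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import SIGNALS, WindowSet
from .errors import ConfigurationError, DataError
from .protocol import QUESTIONS


@dataclass
class JointHistogram:
    """Equal-width 2-D histogram with consistent marginals."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    joint: np.ndarray  # (n_bins, n_bins) counts

    @property
    def n(self) -> int:
        return int(self.joint.sum())

    @property
    def marginal_x(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def _range(v: np.ndarray) -> tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:  # degenerate: widen so everything lands in one bin
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def joint_histogram(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> JointHistogram:
    """Bin two paired samples on equal-width grids over their observed ranges."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise DataError("need at least 2 paired samples")
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    joint, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins, range=[_range(x), _range(y)])
    return JointHistogram(x_edges=x_edges, y_edges=y_edges, joint=joint)


def mutual_information(h: JointHistogram) -> float:
    """Plug-in mutual information of a joint histogram, in bits.

    I = sum over occupied cells of p(x,y) log2[p(x,y) / (p(x) p(y))];
    empty cells are skipped, so independent (outer-product) tables give 0.
    """
    n = h.n
    if n <= 0:
        raise DataError("empty histogram")
    p = h.joint / n
    px = h.marginal_x / n
    py = h.marginal_y / n
    outer = px[:, None] * py[None, :]
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))


def quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based bin labels (equal-occupancy bins); used for the optional
    quantile-binning MI estimator, which is invariant to monotone transforms."""
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * n_bins) // x.size


def mi_matrix(
    windows: WindowSet,
    question: str,
    signal: str,
    n_bins: int = 10,
    binning: str = "width",
) -> pd.DataFrame:
    """Symmetric channel x channel MI matrix (bits) for one question/signal.

    Per channel, the normalized samples of all the question's task windows
    (across trials and participants) are concatenated; the diagonal holds
    each channel's self-information H(X) under the same binning.
    """
    task = windows.select(question=question, task_only=True)
    if len(task) == 0:
        raise DataError(f"no task windows for question {question!r}")
    channels = task.channels
    series = {
        ch: np.concatenate([w.values[signal][i] for w in task])
        for i, ch in enumerate(channels)
    }
    if binning == "quantile":
        series = {ch: quantile_bin(v, n_bins).astype(float) for ch, v in series.items()}
    elif binning != "width":
        raise ConfigurationError(f"unknown binning {binning!r}")

    m = np.zeros((len(channels), len(channels)))
    for i, ci in enumerate(channels):
        for j in range(i, len(channels)):
            mi = mutual_information(joint_histogram(series[ci], series[channels[j]], n_bins))
            m[i, j] = m[j, i] = mi
    return pd.DataFrame(m, index=list(channels), columns=list(channels))


def channel_scores(m: pd.DataFrame) -> pd.Series:
    """Mean off-diagonal MI per channel — the retention criterion."""
    vals = m.to_numpy().copy()
    np.fill_diagonal(vals, np.nan)
    return pd.Series(np.nanmean(vals, axis=1), index=m.index)


def retain_channels(
    m: pd.DataFrame,
    k: int = 7,
    mode: str = "topk",
    threshold: float | None = None,
) -> list[str]:
    """Retain the most informative channels of one MI matrix.

    ``topk`` keeps the k channels with the highest mean off-diagonal MI
    (ties broken by lexicographic label); ``threshold`` keeps channels whose
    mean MI exceeds the given value.  The returned list is sorted by label.
    """
    scores = channel_scores(m)
    if mode == "topk":
        if not 1 <= k <= len(scores):
            raise ConfigurationError(f"k={k} out of range [1, {len(scores)}]")
        order = sorted(scores.index, key=lambda ch: (-scores[ch], ch))
        kept = order[:k]
    elif mode == "threshold":
        if threshold is None:
            raise ConfigurationError("threshold mode requires a threshold value")
        kept = [ch for ch in scores.index if scores[ch] > threshold]
    else:
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    return sorted(kept)


def pooled_retention(matrices: list[pd.DataFrame], k: int = 7) -> list[str]:
    """Top-k channels by mean off-diagonal MI pooled over several matrices.

    Used to fix one analysis channel set for the cross-question feature
    table while the per-(question, signal) selections are reported alongside.
    """
    pooled = sum(m for m in matrices) / len(matrices)
    return retain_channels(pooled, k=k)


@dataclass
class ChannelSelection:
    """Retained channels per (question, signal) plus per-question intersections."""

    retained: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def common(self, question: str) -> list[str]:
        sets = [
            set(self.retained[(question, sig)])
            for sig in SIGNALS
            if (question, sig) in self.retained
        ]
        if len(sets) < len(SIGNALS):
            missing = [s for s in SIGNALS if (question, s) not in self.retained]
            raise DataError(f"question {question!r} missing signals {missing}")
        return sorted(set.intersection(*sets))

    def channels_for(self, question: str) -> list[str]:
        """Union of the three signals' retained channels (analysis channel set)."""
        sets = [set(self.retained[(question, sig)]) for sig in SIGNALS]
        return sorted(set.union(*sets))

    def to_dict(self) -> dict:
        out: dict[str, dict[str, list[str]]] = {}
        questions = dict.fromkeys(q for q, _ in self.retained)
        for q in questions:
            out[q] = {sig: self.retained[(q, sig)] for sig in SIGNALS}
            out[q]["common"] = self.common(q)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def common_channels(selection: ChannelSelection) -> dict[str, list[str]]:
    """Per-question intersection of the three signals' retained channel sets."""
    questions = dict.fromkeys(q for q, _ in selection.retained)
    return {q: selection.common(q) for q in questions}


def select_channels(
    windows: WindowSet,
    n_bins: int = 10,
    k: int = 7,
    mode: str = "topk",
    threshold: float | None = None,
    questions: tuple[str, ...] = QUESTIONS,
    binning: str = "width",
) -> ChannelSelection:
    """Run the MI screen for every question and signal."""
    selection = ChannelSelection()
    for q in questions:
        for sig in SIGNALS:
            m = mi_matrix(windows, q, sig, n_bins=n_bins, binning=binning)
            selection.retained[(q, sig)] = retain_channels(m, k=k, mode=mode, threshold=threshold)
    return selection
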