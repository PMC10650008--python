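"""Per-window statistical and information-theoretic features.

Nine features per (channel, signal, window): window duration ("time"),
mean, median, population variance, range, excess kurtosis, Fisher–Pearson
skewness, Shannon entropy of a histogram (bits) and approximate entropy
(nats, embedding m, tolerance r = r_factor * SD, Chebyshev distance,
self-matches included).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .containers import SIGNALS, WindowSet
from .errors import ConfigurationError, DataError

FEATURE_NAMES: tuple[str, ...] = (
    "time",
    "mean",
    "median",
    "variance",
    "range",
    "kurtosis",
    "skewness",
    "entropy",
    "apen",
)


def shannon_entropy(x: np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy (bits) of an equal-width histogram of ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise DataError("cannot compute entropy of an empty vector")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r) in nats.

    Phi^m(r) is the average log fraction of m-length templates within
    Chebyshev distance r of each template (self-matches included).  The
    double loop over template pairs is vectorized; results match the naive
    O(N^2) definition exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    if r <= 0:
        raise ConfigurationError("ApEn tolerance r must be positive")
    if x.size <= m + 1:
        raise DataError(f"ApEn needs more than m+1={m + 1} samples, got {x.size}")

    def phi(mm: int) -> float:
        n_templates = x.size - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        # pairwise Chebyshev distances between templates
        dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        frac = (dist <= r).sum(axis=1) / n_templates
        return float(np.mean(np.log(frac)))

    return phi(m) - phi(m + 1)


def extract_features(
    x: np.ndarray,
    times: np.ndarray,
    n_bins: int = 10,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
) -> dict[str, float]:
    """The nine-feature vector of one window's samples.

    "time" is the window duration in seconds (sample count x sample period).
    ApEn uses tolerance r = ``apen_r_factor`` x SD; a constant window (SD 0)
    has ApEn 0 by the regularity limit.
    """
    x = np.asarray(x, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    if x.size < apen_m + 2:
        raise DataError(f"window of {x.size} samples is too short for features")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    # constant windows (range 0): shape statistics are defined as 0
    sd = 0.0 if x.max() == x.min() else float(x.std())
    apen = 0.0 if sd == 0.0 else approximate_entropy(x, m=apen_m, r=apen_r_factor * sd)
    return {
        "time": x.size * dt,
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "variance": float(x.var()) if sd > 0 else 0.0,
        "range": float(x.max() - x.min()),
        "kurtosis": float(_kurtosis(x, fisher=True, bias=True)) if sd > 0 else 0.0,
        "skewness": float(_skew(x, bias=True)) if sd > 0 else 0.0,
        "entropy": shannon_entropy(x, n_bins=n_bins),
        "apen": apen,
    }


def feature_table(
    windows: WindowSet,
    channels: list[str] | None = None,
    signals: tuple[str, ...] = SIGNALS,
    n_bins: int = 10,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
    classes: int = 16,
) -> pd.DataFrame:
    """Windows x (channel x signal x 9 features) table with labels.

    Feature columns are named ``{channel}_{signal}_{feature}``; identifier
    columns (participant, trial_index, question, stage, saturation, label)
    come first.  Column count is len(channels) x len(signals) x 9 with no
    missing cells.
    """
    if channels is None:
        channels = list(windows.channels)
    missing = [ch for ch in channels if ch not in windows.channels]
    if missing:
        raise DataError(f"channels {missing} not present in the window set")
    idx = [windows.channels.index(ch) for ch in channels]

    rows = []
    for w in windows:
        row: dict[str, object] = {
            "participant": w.participant,
            "trial_index": w.trial_index,
            "question": w.question,
            "stage": w.stage,
            "saturation": w.saturation,
            "label": w.label(classes),
        }
        for ch, ci in zip(channels, idx):
            for sig in signals:
                feats = extract_features(
                    w.values[sig][ci],
                    w.time,
                    n_bins=n_bins,
                    apen_m=apen_m,
                    apen_r_factor=apen_r_factor,
                )
                for name, val in feats.items():
                    row[f"{ch}_{sig}_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


ID_COLUMNS: tuple[str, ...] = (
    "participant",
    "trial_index",
    "question",
    "stage",
    "saturation",
    "label",
)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, feature_names)."""
    feature_cols = [c for c in table.columns if c not in ID_COLUMNS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    return X, y, feature_cols
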