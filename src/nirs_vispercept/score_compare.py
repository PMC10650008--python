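"""High- vs low-score group comparison of hemodynamic responses.

Questionnaire scores for a question are split at their mean (score > mean
-> high group, score <= mean -> low group).  Per channel and signal the
participant-level mean of the task-window samples is the unit of analysis
(avoiding window-level pseudoreplication), compared between groups with
Welch's two-sample t-test (Mann–Whitney optional), optionally with
Benjamini–Hochberg correction across channels.

The windows fed to this comparison should come from the band-passed,
*unnormalized* hemoglobin series: per-participant min–max normalization
maps every participant onto [0, 1] and would cancel exactly the
between-participant amplitude difference under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SIGNALS, WindowSet
from .errors import ConfigurationError, DataError


def split_scores(scores: pd.DataFrame, question: str) -> dict[str, str]:
    """Mean split of one question's scores: participant -> "high" / "low".

    Ties at the mean go to the low group.  Raises if either group would be
    empty (all scores equal) or fewer than two participants have scores.
    """
    sub = scores.loc[scores["question"] == question]
    sub = sub[np.isfinite(sub["score"])]
    if len(sub) < 2:
        raise DataError(f"need >= 2 finite scores for question {question!r}")
    mean = sub["score"].mean()
    grouping = {
        str(r.participant): ("high" if r.score > mean else "low") for r in sub.itertuples()
    }
    groups = set(grouping.values())
    if groups != {"high", "low"}:
        raise DataError(
            f"degenerate mean split for question {question!r}: only {sorted(groups)} group(s)"
        )
    return grouping


def participant_task_means(
    windows: WindowSet, question: str, statistic: str = "mean", baseline: bool = True
) -> pd.DataFrame:
    """Per-participant summary of task-window samples, per (signal, channel).

    ``statistic`` is the within-participant window summary: "mean" (default),
    "peak" (max) or "range" (max - min), pooled over all the question's task
    windows.  With ``baseline=True`` (default) the mean over the same trials'
    fixation windows is subtracted: band-pass filtering removes the
    session-mean response level, so the rest-referenced statistic — standard
    practice for block designs — is what actually tracks response amplitude.
    Returns a participant x MultiIndex(signal, channel) frame.
    """
    if statistic not in ("mean", "peak", "range"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    task = windows.select(question=question, task_only=True)
    if len(task) == 0:
        raise DataError(f"no task windows for question {question!r}")
    rest = WindowSet(
        [
            w
            for w in windows
            if w.question == question and w.stage in ("baseline", "fixation")
        ],
        windows.channels,
        windows.signals,
        windows.mode,
    )
    rows: dict[str, dict[tuple[str, str], float]] = {}
    for pid in task.participants():
        per_p = task.select(participant=pid)
        per_p_rest = rest.select(participant=pid)
        row: dict[tuple[str, str], float] = {}
        for sig in task.signals:
            pooled = np.concatenate([w.values[sig] for w in per_p], axis=1)  # (C, n)
            if statistic == "mean":
                vals = pooled.mean(axis=1)
            elif statistic == "peak":
                vals = pooled.max(axis=1)
            else:
                vals = pooled.max(axis=1) - pooled.min(axis=1)
            if baseline and statistic != "range" and len(per_p_rest) > 0:
                rest_pooled = np.concatenate([w.values[sig] for w in per_p_rest], axis=1)
                vals = vals - rest_pooled.mean(axis=1)
            for ch, v in zip(task.channels, vals):
                row[(sig, ch)] = float(v)
        rows[pid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["signal", "channel"])
    return frame


def welch_table(
    means: pd.DataFrame,
    grouping: dict[str, str],
    test: str = "welch",
    fdr: bool = False,
) -> pd.DataFrame:
    """Group comparison per (signal, channel) column of a participant-means frame.

    Returns columns: signal, channel, mean_high, mean_low, p_value, n_high,
    n_low.  ``test`` is "welch" (unequal-variance t) or "mannwhitney";
    ``fdr=True`` adds Benjamini–Hochberg adjusted p-values (``p_adj``).
    """
    high = [p for p in means.index if grouping.get(p) == "high"]
    low = [p for p in means.index if grouping.get(p) == "low"]
    if len(high) < 2 or len(low) < 2:
        raise DataError(f"need >= 2 participants per group, got {len(high)}/{len(low)}")
    rows = []
    for sig, ch in means.columns:
        a = means.loc[high, (sig, ch)].to_numpy()
        b = means.loc[low, (sig, ch)].to_numpy()
        if test == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
        elif test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ConfigurationError(f"unknown test {test!r}")
        rows.append(
            {
                "signal": sig,
                "channel": ch,
                "mean_high": float(a.mean()),
                "mean_low": float(b.mean()),
                "p_value": float(res.pvalue),
                "n_high": len(a),
                "n_low": len(b),
            }
        )
    table = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def group_difference(
    windows: WindowSet,
    grouping: dict[str, str],
    question: str,
    statistic: str = "mean",
    test: str = "welch",
    fdr: bool = False,
    baseline: bool = True,
) -> pd.DataFrame:
    """High- vs low-score comparison for one question, per channel and signal."""
    means = participant_task_means(windows, question, statistic=statistic, baseline=baseline)
    table = welch_table(means, grouping, test=test, fdr=fdr)
    table.insert(0, "question", question)
    return table


def group_curves(windows: WindowSet, grouping: dict[str, str], question: str) -> pd.DataFrame:
    """Group-average task-window time courses per channel and signal.

    Curves are averaged across a group's participants and trials on the
    within-window time axis, then jointly min–max scaled to [0, 1] per
    (signal, channel) across both groups so the groups stay comparable.
    """
    task = windows.select(question=question, task_only=True)
    n_min = min(w.time.size for w in task)
    dt = float(np.median(np.diff(task.windows[0].time)))
    rows = []
    for sig in task.signals:
        for ci, ch in enumerate(task.channels):
            curves = {}
            for grp in ("high", "low"):
                stack = [
                    w.values[sig][ci][:n_min]
                    for w in task
                    if grouping.get(w.participant) == grp
                ]
                curves[grp] = np.mean(stack, axis=0)
            lo = min(c.min() for c in curves.values())
            hi = max(c.max() for c in curves.values())
            span = (hi - lo) or 1.0
            for grp, curve in curves.items():
                for i, v in enumerate(curve):
                    rows.append(
                        {
                            "question": question,
                            "signal": sig,
                            "channel": ch,
                            "group": grp,
                            "time_s": i * dt,
                            "value": (v - lo) / span,
                        }
                    )
    return pd.DataFrame(rows)
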