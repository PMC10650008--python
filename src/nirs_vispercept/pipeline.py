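"""End-to-end orchestration: simulate/ingest -> MBLL -> prep -> screen ->
features -> classify -> compare, from a single seeded configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channel_screen import mi_matrix, pooled_retention, select_channels
from .classify import build_report, knn_crossval
from .config import MBLLConfig, SimulationConfig, config_from_mapping
from .containers import RawIntensityRecording, WindowSet, concat_window_sets
from .errors import ConfigurationError, DataError
from .features import feature_matrix, feature_table
from .mbll import invert_mbll
from .preprocess import bandpass, normalize_series, segment_windows
from .protocol import QUESTIONS, TrialSchedule
from .score_compare import group_difference, split_scores
from .simulate import Study, simulate_study

logger = logging.getLogger(__name__)

_SECTION_KEYS = {
    "simulate": None,  # validated by SimulationConfig itself
    "optics": None,  # validated by MBLLConfig itself
    "prep": {"band_low", "band_high", "band_order", "window_mode"},
    "channels": {"bins", "k", "mode", "threshold", "binning"},
    "features": {"bins", "apen_m", "apen_r_factor"},
    "classify": {"classes", "n_folds", "k_grid", "n_features", "rfe_step", "inner_folds"},
    "compare": {"test", "fdr", "statistic"},
}


@dataclass
class PipelineConfig:
    """One config for the whole pipeline; unknown keys are rejected at load."""

    simulate: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    prep: dict = field(default_factory=dict)
    channels: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)
    input_dir: str | None = None
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            values = getattr(self, section)
            if allowed is not None:
                unknown = set(values) - allowed
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in section {section!r}: {sorted(unknown)}"
                    )
        # fail fast: every downstream precondition checkable at load time
        self.simulation_config()
        self.optics_config()
        fs = self.simulation_config().sampling_rate
        low = self.prep.get("band_low", 0.01)
        high = self.prep.get("band_high", 0.5)
        if not (0.0 < low < high < fs / 2.0):
            raise ConfigurationError(
                f"band ({low}, {high}) Hz invalid for sampling rate {fs} Hz"
            )
        if self.prep.get("window_mode", "per_stage") not in ("task_baseline", "per_stage"):
            raise ConfigurationError("window_mode must be 'task_baseline' or 'per_stage'")
        if self.classify.get("classes", 16) not in (16, 4):
            raise ConfigurationError("classes must be 16 or 4")

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.simulate)
        overrides.setdefault("seed", self.seed)
        return config_from_mapping(SimulationConfig, overrides)

    def optics_config(self) -> MBLLConfig:
        return config_from_mapping(MBLLConfig, self.optics)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {
            "simulate",
            "optics",
            "prep",
            "channels",
            "features",
            "classify",
            "compare",
            "input_dir",
            "seed",
            "out_dir",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def write_study(study: Study, out_dir: Path) -> list[str]:
    """Write the raw-data dialects: per-participant intensity CSV and events
    TSV, plus one scores CSV."""
    part_dir = out_dir / "participants"
    part_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in study.participants:
        if p.recording is None:
            raise DataError("study was simulated without optics; no intensities to write")
        ipath = part_dir / f"{p.participant}_intensity.csv"
        epath = part_dir / f"{p.participant}_events.tsv"
        p.recording.to_csv(ipath)
        p.schedule.to_tsv(epath)
        written += [str(ipath), str(epath)]
    spath = out_dir / "scores.csv"
    study.scores_frame().to_csv(spath, index=False)
    written.append(str(spath))
    return written


def load_study_inputs(
    input_dir: Path, wavelengths=(760.0, 850.0)
) -> tuple[list[tuple[str, RawIntensityRecording, TrialSchedule]], pd.DataFrame]:
    """Read the raw-data dialects written by :func:`write_study`."""
    part_dir = Path(input_dir) / "participants"
    entries = []
    for ipath in sorted(part_dir.glob("*_intensity.csv")):
        pid = ipath.name.replace("_intensity.csv", "")
        epath = part_dir / f"{pid}_events.tsv"
        if not epath.exists():
            raise DataError(f"missing events file for participant {pid!r}")
        entries.append(
            (
                pid,
                RawIntensityRecording.from_csv(ipath, wavelengths=wavelengths),
                TrialSchedule.from_tsv(epath),
            )
        )
    if not entries:
        raise DataError(f"no participant recordings under {part_dir}")
    scores = pd.read_csv(Path(input_dir) / "scores.csv")
    return entries, scores


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Re-running with the same config and seed is bit-identical: all
    randomness flows from the master seed through named substreams.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "stages": {},
    }
    optics = cfg.optics_config()

    # -- stage 1: simulate or ingest ---------------------------------------
    if cfg.input_dir is None:
        sim_cfg = cfg.simulation_config()
        study = simulate_study(sim_cfg, optics=optics)
        files = write_study(study, out)
        sessions = [
            (p.participant, p.recording, p.schedule) for p in study.participants
        ]
        scores = study.scores_frame()
        manifest["stages"]["simulate"] = {"participants": len(study), "files": files}
    else:
        sessions, scores = load_study_inputs(Path(cfg.input_dir), optics.wavelengths)
        manifest["stages"]["ingest"] = {
            "participants": len(sessions),
            "input_dir": str(cfg.input_dir),
        }
    logger.info("stage 1 done: %d sessions", len(sessions))

    # -- stages 2-3: MBLL, filter, normalize, window -----------------------
    mode = cfg.prep.get("window_mode", "per_stage")
    low = cfg.prep.get("band_low", 0.01)
    high = cfg.prep.get("band_high", 0.5)
    order = cfg.prep.get("band_order", 2)
    norm_sets, raw_sets = [], []
    for pid, rec, schedule in sessions:
        hemo = invert_mbll(rec, optics)
        filtered = bandpass(hemo, low_hz=low, high_hz=high, order=order)
        raw_sets.append(segment_windows(filtered, schedule, mode=mode, participant=pid))
        norm_sets.append(
            segment_windows(normalize_series(filtered), schedule, mode=mode, participant=pid)
        )
    windows_norm = concat_window_sets(norm_sets)
    windows_raw = concat_window_sets(raw_sets)
    wpath = out / "windows.csv"
    windows_norm.to_frame().to_csv(wpath, index=False)
    manifest["stages"]["prep"] = {"windows": len(windows_norm), "file": str(wpath)}
    logger.info("stage 2-3 done: %d windows (%s mode)", len(windows_norm), mode)

    # -- stage 4: MI channel screen ----------------------------------------
    bins = cfg.channels.get("bins", 10)
    k = cfg.channels.get("k", 7)
    selection = select_channels(
        windows_norm,
        n_bins=bins,
        k=k,
        mode=cfg.channels.get("mode", "topk"),
        threshold=cfg.channels.get("threshold"),
        binning=cfg.channels.get("binning", "width"),
    )
    spath = out / "channel_selection.json"
    selection.to_json(spath)
    matrices = [
        mi_matrix(windows_norm, q, sig, n_bins=bins)
        for q in QUESTIONS
        for sig in windows_norm.signals
    ]
    analysis_channels = pooled_retention(matrices, k=k)
    manifest["stages"]["select_channels"] = {
        "file": str(spath),
        "analysis_channels": analysis_channels,
    }
    logger.info("stage 4 done: analysis channels %s", analysis_channels)

    # -- stage 5: features --------------------------------------------------
    table = feature_table(
        windows_norm,
        channels=analysis_channels,
        n_bins=cfg.features.get("bins", 10),
        apen_m=cfg.features.get("apen_m", 2),
        apen_r_factor=cfg.features.get("apen_r_factor", 0.2),
        classes=cfg.classify.get("classes", 16),
    )
    fpath = out / "features.csv"
    table.to_csv(fpath, index=False)
    manifest["stages"]["features"] = {
        "rows": len(table),
        "columns": table.shape[1],
        "file": str(fpath),
    }
    logger.info("stage 5 done: feature table %s", table.shape)

    # -- stage 6: classification -------------------------------------------
    X, y, _ = feature_matrix(table)
    clf_seed = int(np.random.SeedSequence(cfg.seed).spawn(2)[1].generate_state(1)[0] % (2**31))
    result = knn_crossval(
        X,
        y,
        k_grid=tuple(cfg.classify.get("k_grid", (1, 3, 5, 7, 9))),
        n_folds=cfg.classify.get("n_folds", 5),
        seed=clf_seed,
        n_features=cfg.classify.get("n_features", 30),
        rfe_step=cfg.classify.get("rfe_step", 0.1),
        inner_folds=cfg.classify.get("inner_folds", 3),
    )
    report = build_report(y, result.predictions, elapsed_s=result.elapsed_s)
    rpath = out / "classification_report.csv"
    report.to_csv(rpath)
    with open(out / "classification_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    manifest["stages"]["classify"] = {
        "mean_accuracy_pct": round(float(report.summary_mean["accuracy"]), 1),
        "file": str(rpath),
    }
    logger.info(
        "stage 6 done: mean accuracy %.1f%%", report.summary_mean["accuracy"]
    )

    # -- stage 7: score-group comparison ------------------------------------
    tables = []
    for q in QUESTIONS:
        try:
            grouping = split_scores(scores, q)
        except DataError as exc:
            logger.warning("skipping comparison for %s: %s", q, exc)
            continue
        tables.append(
            group_difference(
                windows_raw,
                grouping,
                q,
                statistic=cfg.compare.get("statistic", "mean"),
                test=cfg.compare.get("test", "welch"),
                fdr=cfg.compare.get("fdr", False),
            )
        )
    comparison = pd.concat(tables, ignore_index=True)
    cpath = out / "score_comparison.csv"
    comparison.to_csv(cpath, index=False)
    manifest["stages"]["compare"] = {
        "rows": len(comparison),
        "max_p": float(comparison["p_value"].max()),
        "file": str(cpath),
    }
    logger.info("stage 7 done: max p = %.3g", comparison["p_value"].max())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_fixtures(out_dir, seed: int = 0, size: str = "tiny") -> Path:
    """Write a self-contained fixture directory of raw inputs.

    ``tiny`` simulates 2 participants over a reduced 4-trial design (unit
    tests); ``full`` simulates the 29-participant, 16-trial sessions.
    """
    out = Path(out_dir)
    if size == "tiny":
        sim_cfg = SimulationConfig(
            n_participants=2, saturations=("low",), n_repeats=1, seed=seed
        )
    elif size == "full":
        sim_cfg = SimulationConfig(seed=seed)
    else:
        raise ConfigurationError(f"unknown fixture size {size!r}")
    study = simulate_study(sim_cfg, optics=MBLLConfig())
    write_study(study, out)
    return out
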