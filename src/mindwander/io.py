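"""Readers/writers and run configuration for the pipeline stages.

On-disk conventions: per-subject event tables as tab-separated text,
epochs as a ``.npy`` array (trials x channels x samples) with a JSON
sidecar carrying channel names, sampling rate, the time-zero index and
per-trial metadata; feature tables as comma-separated text with a fixed
header; evaluation results as JSON.  A run configuration is a YAML file
whose sections mirror the pipeline stages, and one global seed fans out
deterministically to per-stage child seeds so any stage can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import BalanceConfig
from .classify import ModelSpec
from .features import FEATURE_COLUMNS, FeatureSpec
from .simulate import Block, Epoch, GeneratorConfig, SubjectSession


def child_seed(seed: int | None, stage: str) -> int | None:
    """Deterministic per-stage seed derived from the global one (< 2**31)."""
    if seed is None:
        return None
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# events / epochs

def write_events(session: SubjectSession, path) -> None:
    """Tab-separated event table: one row per trial, cumulative onsets."""
    rows = []
    block_start = 0.0
    for b_idx, block in enumerate(session.blocks):
        onsets = (block.onsets_s if block.onsets_s is not None
                  else 1.2 * np.arange(len(block.trials)))
        for trial, onset in zip(block.trials, onsets):
            rows.append({
                "onset_s": round(block_start + float(onset), 4),
                "duration_s": 0.2,
                "tone_type": trial.tone_type,
                "block": b_idx,
                "probe_response": block.probe_response,
            })
        block_start += block.duration_s
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_epochs(session: SubjectSession, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.stack([t.data for b in session.blocks for t in b.trials])
    np.save(directory / f"{session.subject_id}_epochs.npy", data)
    first = session.blocks[0].trials[0]
    meta = {
        "subject_id": session.subject_id,
        "shape": list(data.shape),
        "channels": list(session.channels),
        "sampling_rate_hz": session.sampling_rate_hz,
        "time_zero_index": int(np.argmin(np.abs(first.times_ms))),
        "times_ms_start": float(first.times_ms[0]),
        "trials": [
            {"tone_type": t.tone_type, "block": b_idx,
             "artifact": bool(t.artifact), "probe_response": b.probe_response}
            for b_idx, b in enumerate(session.blocks) for t in b.trials
        ],
    }
    with open(directory / f"{session.subject_id}_epochs.json", "w") as fh:
        json.dump(meta, fh)


def read_epochs(directory, subject_id: str) -> SubjectSession:
    directory = Path(directory)
    data = np.load(directory / f"{subject_id}_epochs.npy")
    with open(directory / f"{subject_id}_epochs.json") as fh:
        meta = json.load(fh)
    fs = meta["sampling_rate_hz"]
    times = meta["times_ms_start"] + np.arange(data.shape[-1]) / fs * 1000.0
    channels = tuple(meta["channels"])
    blocks: dict[int, Block] = {}
    for i, tr in enumerate(meta["trials"]):
        b = tr["block"]
        if b not in blocks:
            blocks[b] = Block([], tr["probe_response"], duration_s=0.0)
        ep = Epoch(data[i], times, channels, tr["tone_type"], b,
                   len(blocks[b].trials), bool(tr["artifact"]))
        blocks[b].trials.append(ep)
    ordered = [blocks[k] for k in sorted(blocks)]
    return SubjectSession(subject_id, ordered, channels, fs)


# ---------------------------------------------------------------------------
# feature tables

def write_features(table: pd.DataFrame, path) -> None:
    _validate_features(table)
    # %.17g guarantees exact float64 round-trips through text
    table[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    _validate_features(table)
    return table


def _validate_features(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    bad = set(table["label"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"labels must be 0 (on task) or 1 (mind wandering); "
                         f"found {sorted(bad)}")
    if table["normalized"].nunique() > 1:
        raise ValueError("mixed normalized flags in one table")
    # raw SDs are non-negative; after on-task centring they may not be
    if (table["normalized"] == 0).all() and (
            table[["n1_sd", "p3_sd"]] < 0).any().any():
        raise ValueError("negative standard deviations in feature table")


# ---------------------------------------------------------------------------
# results

def write_results(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run bit-for-bit."""

    seed: int | None = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    evaluation_mode: str = "across"  # "within" or "across"
    normalization: str = "per_subject"
    run_stats: bool = True
    run_ablation: bool = False
    output_dir: str = "mindwander_run"


def save_config(config: RunConfig, path) -> None:
    doc = {
        "seed": config.seed,
        "evaluation_mode": config.evaluation_mode,
        "normalization": config.normalization,
        "run_stats": config.run_stats,
        "run_ablation": config.run_ablation,
        "output_dir": config.output_dir,
        "generator": dataclasses.asdict(config.generator),
        "features": dataclasses.asdict(config.features),
        "balance": dataclasses.asdict(config.balance),
        "model": dataclasses.asdict(config.model),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    def build(cls, section):
        data = doc.get(section) or {}
        if cls is FeatureSpec:
            from .features import ComponentWindow
            for key in ("n1", "p3"):
                if key in data and isinstance(data[key], dict):
                    win = data[key]
                    data[key] = ComponentWindow(
                        tuple(win["window_ms"]), tuple(win["channels"]),
                        int(win["polarity"]))
        data = {k: (tuple(v) if isinstance(v, list) else v)
                for k, v in data.items()}
        return cls(**data)

    return RunConfig(
        seed=doc.get("seed", 0),
        generator=build(GeneratorConfig, "generator"),
        features=build(FeatureSpec, "features"),
        balance=build(BalanceConfig, "balance"),
        model=build(ModelSpec, "model"),
        evaluation_mode=doc.get("evaluation_mode", "across"),
        normalization=doc.get("normalization", "per_subject"),
        run_stats=doc.get("run_stats", True),
        run_ablation=doc.get("run_ablation", False),
        output_dir=doc.get("output_dir", "mindwander_run"),
    )
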