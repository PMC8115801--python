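"""Block-level ERP features: N1/P3 peak mean and variability.

Each block contributes one feature row: the mean and sample standard
deviation, across the (up to) 10 artifact-free trials preceding the
thought probe, of two per-trial peak measures — the N1 minimum amplitude
(80-120 ms, fronto-central sites FC1/FCz/FC2) and the P3 maximum
amplitude (400-600 ms, parietal sites P1/Pz/P2).  Trials are band-pass
filtered at 1-15 Hz (zero-phase) and baseline-corrected to the -200..0 ms
pre-stimulus mean before peak extraction.  Classification features use
standard tones only; rare targets are too few per block for a stable
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .simulate import Epoch, Block, SubjectSession, STANDARD

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("n1_mean", "n1_sd", "p3_mean", "p3_sd")

FEATURE_COLUMNS = ["subject_id", "block", "label",
                   "n1_mean", "n1_sd", "p3_mean", "p3_sd",
                   "n_trials_used", "normalized"]


@dataclass
class ComponentWindow:
    window_ms: tuple[float, float]
    channels: tuple[str, ...]
    polarity: int  # -1: take the minimum; +1: take the maximum


@dataclass
class FeatureSpec:
    """Measurement windows, sites, and preprocessing of the ERP features."""

    filter_band_hz: tuple[float, float] = (1.0, 15.0)
    filter_order: int = 4
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    n1: ComponentWindow = field(default_factory=lambda: ComponentWindow(
        (80.0, 120.0), ("FC1", "FCz", "FC2"), -1))
    p3: ComponentWindow = field(default_factory=lambda: ComponentWindow(
        (400.0, 600.0), ("P1", "Pz", "P2"), +1))
    trials_per_block: int = 10
    standard_only: bool = True
    min_trials: int = 2  # sample SD is undefined below this


def bandpass_filter(epoch: Epoch, band_hz: tuple[float, float],
                    order: int = 4) -> Epoch:
    """Zero-phase Butterworth band-pass, applied per channel."""
    lo, hi = band_hz
    fs = 1000.0 / float(np.diff(epoch.times_ms[:2])[0])
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} invalid for Nyquist {nyq:g} Hz")
    sos = butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    return epoch.copy_with(sosfiltfilt(sos, epoch.data, axis=-1))


def baseline_correct(epoch: Epoch, window_ms: tuple[float, float]) -> Epoch:
    """Subtract each channel's mean over the pre-stimulus window."""
    lo, hi = window_ms
    t = epoch.times_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"baseline window {window_ms} outside epoch")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return epoch.copy_with(epoch.data - epoch.data[:, mask].mean(axis=1,
                                                                 keepdims=True))


def extract_peak(epoch: Epoch, channels: tuple[str, ...],
                 window_ms: tuple[float, float], polarity: int) -> float:
    """Average the named channels, then take the extremum in the window.

    Window endpoints are inclusive; polarity -1 returns the minimum,
    +1 the maximum.
    """
    try:
        idx = [epoch.channels.index(ch) for ch in channels]
    except ValueError as err:
        raise KeyError(f"channel missing from epoch montage: {err}") from None
    lo, hi = window_ms
    mask = (epoch.times_ms >= lo) & (epoch.times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    virtual = epoch.data[idx].mean(axis=0)[mask]
    return float(virtual.min() if polarity < 0 else virtual.max())


def select_preprobe_trials(block: Block, n: int = 10) -> list[Epoch]:
    """The last up-to-n artifact-free trials before the probe, in order."""
    if not block.trials:
        raise ValueError("block has no trials")
    clean = [t for t in block.trials if not t.artifact]
    return clean[-n:]


def preprocess_epoch(epoch: Epoch, spec: FeatureSpec) -> Epoch:
    return baseline_correct(bandpass_filter(epoch, spec.filter_band_hz,
                                            spec.filter_order),
                            spec.baseline_window_ms)


def _batch_peaks(trials: list[Epoch], spec: FeatureSpec
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial N1/P3 peaks with the filter applied to all trials at once.

    Equivalent to preprocessing each epoch separately (the zero-phase
    filter and baseline act per trace), but one vectorised pass.
    """
    first = trials[0]
    data = np.stack([t.data for t in trials])  # (n_trials, n_ch, n_samp)
    fs = 1000.0 / float(np.diff(first.times_ms[:2])[0])
    nyq = fs / 2.0
    lo, hi = spec.filter_band_hz
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {spec.filter_band_hz} invalid for Nyquist {nyq:g} Hz")
    sos = butter(spec.filter_order, spec.filter_band_hz, btype="bandpass",
                 fs=fs, output="sos")
    data = sosfiltfilt(sos, data, axis=-1)
    t = first.times_ms
    b_lo, b_hi = spec.baseline_window_ms
    base = (t >= b_lo) & (t <= b_hi)
    data = data - data[:, :, base].mean(axis=-1, keepdims=True)
    peaks = []
    for window in (spec.n1, spec.p3):
        idx = [first.channels.index(ch) for ch in window.channels]
        mask = (t >= window.window_ms[0]) & (t <= window.window_ms[1])
        virtual = data[:, idx, :].mean(axis=1)[:, mask]
        peaks.append(virtual.min(axis=1) if window.polarity < 0
                     else virtual.max(axis=1))
    return peaks[0], peaks[1]


def block_features(block: Block, spec: FeatureSpec,
                   subject_id: str = "", block_index: int = 0) -> dict | None:
    """One feature row from one block, or None if too few usable trials."""
    selected = select_preprobe_trials(block, spec.trials_per_block)
    if spec.standard_only:
        selected = [t for t in selected if t.tone_type == STANDARD]
    if len(selected) < spec.min_trials:
        logger.warning("block %s/%d dropped: only %d usable trials",
                       subject_id, block_index, len(selected))
        return None
    n1_peaks, p3_peaks = _batch_peaks(selected, spec)
    return {
        "subject_id": subject_id,
        "block": block_index,
        "label": block.label,
        "n1_mean": float(n1_peaks.mean()),
        "n1_sd": float(n1_peaks.std(ddof=1)),
        "p3_mean": float(p3_peaks.mean()),
        "p3_sd": float(p3_peaks.std(ddof=1)),
        "n_trials_used": len(selected),
        "normalized": 0,
    }


def session_features(session: SubjectSession,
                     spec: FeatureSpec | None = None) -> pd.DataFrame:
    """Feature table for one subject (one row per retained block)."""
    spec = spec or FeatureSpec()
    rows = []
    for b_idx, block in enumerate(session.blocks):
        row = block_features(block, spec, session.subject_id, b_idx)
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def cohort_features(sessions, spec: FeatureSpec | None = None) -> pd.DataFrame:
    """Concatenated feature tables for an iterable of sessions."""
    spec = spec or FeatureSpec()
    tables = [session_features(s, spec) for s in sessions]
    if not tables:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def normalize_features(table: pd.DataFrame,
                       feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Per-subject, per-feature on-task-mean centring.

    For every subject and every feature, the mean of that subject's
    on-task (label 0) rows is subtracted from all of the subject's rows,
    so on-task rows average to zero and mind-wandering rows express the
    deviation from that subject's attentive baseline.  Idempotent.
    """
    out = table.copy()
    for subject, idx in out.groupby("subject_id").groups.items():
        sub = out.loc[idx]
        on_task = sub[sub["label"] == 0]
        if on_task.empty:
            raise ValueError(f"subject {subject!r} has no on-task blocks; "
                             "cannot normalize")
        out.loc[idx, list(feature_names)] = (
            sub[list(feature_names)] - on_task[list(feature_names)].mean()
        )
    out["normalized"] = 1
    return out
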