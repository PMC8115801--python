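"""Synthetic auditory-oddball EEG sessions with thought-probe labels.

Generates epoched, multichannel EEG for a target-detection paradigm:
frequent standard tones (800 Hz, p = 0.8) and rare targets (1000 Hz,
p = 0.2), organised into blocks that each end in a thought probe labelling
the block "on task" or "mind wandering".  Event-related components (an
early fronto-central N1 and a later parietal P3) are rendered as smooth,
band-limited bumps whose amplitudes are attenuated during mind wandering,
on top of 1/f ("pink") and white sensor noise.

The generator produces epochs directly (stimulus-locked windows of
-1000..+2000 ms at 512 Hz); no continuous record is synthesised, since the
downstream analysis consumes epochs only.  Artifactual trials are marked
with a boolean flag rather than corrupted waveforms — only the exclusion
logic matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

ON_TASK = "on_task"
MIND_WANDERING = "mind_wandering"
STANDARD = "standard"
TARGET = "target"

#: settings of the downstream ERP analysis chain, used to pre-condition
#: component templates so that filtering + baselining preserves their peaks
_ANALYSIS_BAND_HZ = (1.0, 15.0)
_ANALYSIS_FILTER_ORDER = 4
_BASELINE_WINDOW_MS = (-200.0, 0.0)
_TEMPLATE_REFINE_PASSES = 8


@dataclass
class GeneratorConfig:
    """Cohort/session parameters of the simulated oddball experiment.

    Defaults reproduce the study design: 14 subjects, 25 blocks of
    45-75 s each, 1500 tones total (1200 standard / 300 target) in
    exact-proportion mode, 800-1200 ms inter-trial jitter, 200 ms tones,
    epochs of -1000..+2000 ms sampled at 512 Hz on the six analysis
    electrodes.  Subjects report mind wandering at a rate drawn from a
    Beta distribution with mean ``mw_rate_mean`` truncated to
    ``mw_rate_range``.
    """

    n_subjects: int = 14
    n_blocks: int = 25
    block_duration_range_s: tuple[float, float] = (45.0, 75.0)
    tone_probabilities: tuple[float, float] = (0.8, 0.2)  # (standard, target)
    total_tones: int = 1500
    tone_mode: str = "exact"  # "exact" (global proportions) or "bernoulli"
    iti_range_ms: tuple[float, float] = (800.0, 1200.0)
    tone_duration_ms: float = 200.0
    sampling_rate_hz: float = 512.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 2000.0)
    channels: tuple[str, ...] = ("FC1", "FCz", "FC2", "P1", "Pz", "P2")
    mw_rate_mean: float = 0.55
    mw_rate_sd: float = 0.198
    mw_rate_range: tuple[float, float] = (0.20, 0.88)
    artifact_probability: float = 0.05
    noise_white_sd_uv: float = 4.0
    noise_pink_exponent: float = 1.0
    noise_pink_scale_uv: float = 4.0
    trial_amplitude_jitter: float = 0.3
    subject_gain_sd: float = 0.2
    mw_attenuation: float = 0.3
    # reaction times for target tones (used by the univariate stats only)
    rt_mean_on_task_ms: float = 511.0
    rt_mean_mw_ms: float = 535.0
    rt_trial_sd_ms: float = 60.0
    rt_subject_sd_ms: float = 40.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p_std, p_tgt = self.tone_probabilities
        if not (0.0 <= p_std <= 1.0 and 0.0 <= p_tgt <= 1.0):
            raise ValueError("tone probabilities must lie in [0, 1]")
        if abs(p_std + p_tgt - 1.0) > 1e-9:
            raise ValueError("tone probabilities must sum to 1")
        if self.n_subjects < 1 or self.n_blocks < 1 or self.total_tones < 1:
            raise ValueError("counts must be positive")
        if self.tone_mode not in ("exact", "bernoulli"):
            raise ValueError(f"unknown tone_mode {self.tone_mode!r}")
        lo, hi = self.epoch_window_ms
        if hi <= lo:
            raise ValueError("epoch window must have positive length")
        if not 0.0 <= self.mw_attenuation <= 1.0:
            raise ValueError("mw_attenuation must lie in [0, 1]")
        if not 0.0 <= self.artifact_probability <= 1.0:
            raise ValueError("artifact_probability must lie in [0, 1]")
        r_lo, r_hi = self.mw_rate_range
        if not 0.0 <= r_lo <= r_hi <= 1.0:
            raise ValueError("mw_rate_range must be an ordered pair in [0, 1]")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window_ms
        return int(round((hi - lo) / 1000.0 * self.sampling_rate_hz))

    @property
    def times_ms(self) -> np.ndarray:
        lo, _ = self.epoch_window_ms
        return lo + np.arange(self.n_samples) / self.sampling_rate_hz * 1000.0

    @property
    def trials_per_block_range(self) -> tuple[int, int]:
        """Approximate trial-count range implied by block duration and ITI."""
        mean_gap_s = (self.tone_duration_ms + np.mean(self.iti_range_ms)) / 1000.0
        lo, hi = self.block_duration_range_s
        return int(lo / mean_gap_s), int(math.ceil(hi / mean_gap_s))

    def short_blocks(self) -> "GeneratorConfig":
        """A run-time economy preset: ~13-trial blocks in Bernoulli mode.

        Block-level features use only the last 10 pre-probe trials, so
        shrinking blocks leaves the feature distribution unchanged while
        cutting simulation cost; intended for Monte-Carlo studies.
        """
        return replace(self, tone_mode="bernoulli", block_duration_range_s=(16.0, 20.0))


@dataclass
class ComponentTemplate:
    """One ERP component: a localized bump with state x tone amplitudes.

    ``amplitude_uv`` maps (attention state, tone type) to the peak
    amplitude in microvolts; signs must agree with ``polarity``.  The
    topography maps channel names to gains (unlisted channels get 0).
    """

    name: str
    latency_ms: float
    width_ms: float
    polarity: int  # -1 negative-going, +1 positive-going
    topography: dict[str, float]
    amplitude_uv: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        for key, amp in self.amplitude_uv.items():
            if amp != 0.0 and math.copysign(1.0, amp) != self.polarity:
                raise ValueError(f"amplitude sign for {key} contradicts polarity")

    def amplitude(self, state: str, tone: str) -> float:
        return self.amplitude_uv[(state, tone)]

    @classmethod
    def from_base(
        cls,
        name: str,
        latency_ms: float,
        width_ms: float,
        polarity: int,
        topography: dict[str, float],
        standard_uv: float,
        target_uv: float,
        mw_attenuation: float,
    ) -> "ComponentTemplate":
        if not 0.0 <= mw_attenuation <= 1.0:
            raise ValueError("mw_attenuation must lie in [0, 1]")
        keep = 1.0 - mw_attenuation
        amps = {
            (ON_TASK, STANDARD): standard_uv,
            (ON_TASK, TARGET): target_uv,
            (MIND_WANDERING, STANDARD): standard_uv * keep,
            (MIND_WANDERING, TARGET): target_uv * keep,
        }
        return cls(name, latency_ms, width_ms, polarity, topography, amps)


def default_templates(config: GeneratorConfig) -> dict[str, ComponentTemplate]:
    """The N1/P3 pair used throughout: fronto-central N1, parietal P3.

    Amplitudes are defined at the virtual electrode formed by averaging
    each component's analysis sites, so those sites carry unit gain;
    channels outside a component's patch carry zero.
    """
    att = config.mw_attenuation
    n1 = ComponentTemplate.from_base(
        "N1", latency_ms=100.0, width_ms=20.0, polarity=-1,
        topography={"FC1": 1.0, "FCz": 1.0, "FC2": 1.0},
        standard_uv=-5.0, target_uv=-8.0, mw_attenuation=att,
    )
    p3 = ComponentTemplate.from_base(
        "P3", latency_ms=500.0, width_ms=80.0, polarity=+1,
        topography={"P1": 1.0, "Pz": 1.0, "P2": 1.0},
        standard_uv=6.0, target_uv=12.0, mw_attenuation=att,
    )
    return {"N1": n1, "P3": p3}


@dataclass
class Epoch:
    """One trial: channels x samples (microvolts) around stimulus onset."""

    data: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    tone_type: str
    block_index: int
    trial_index: int
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.channels), len(self.times_ms)):
            raise ValueError("data shape must be (n_channels, n_samples)")

    def copy_with(self, data: np.ndarray) -> "Epoch":
        return Epoch(data, self.times_ms, self.channels, self.tone_type,
                     self.block_index, self.trial_index, self.artifact)


@dataclass
class Block:
    trials: list[Epoch]
    probe_response: str  # ON_TASK or MIND_WANDERING
    duration_s: float
    rts_ms: list[tuple[int, float]] = field(default_factory=list)
    onsets_s: np.ndarray | None = None  # block-relative stimulus onsets

    @property
    def label(self) -> int:
        return 1 if self.probe_response == MIND_WANDERING else 0


@dataclass
class SubjectSession:
    subject_id: str
    blocks: list[Block]
    channels: tuple[str, ...]
    sampling_rate_hz: float
    true_params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)


# ---------------------------------------------------------------------------
# waveform rendering


def gaussian_bump(times_ms: np.ndarray, latency_ms: float, width_ms: float,
                  amplitude_uv: float) -> np.ndarray:
    """Gaussian pulse, truncated to zero beyond four widths from the peak."""
    z = (np.asarray(times_ms, dtype=float) - latency_ms) / width_ms
    wave = amplitude_uv * np.exp(-0.5 * z * z)
    wave[np.abs(z) > 4.0] = 0.0
    return wave


@lru_cache(maxsize=64)
def _band_limited_shape(latency_ms: float, width_ms: float, fs: float,
                        t0: float, n_samples: int) -> np.ndarray:
    """Unit-extremum bump invariant (to ~1%) under the ERP analysis chain.

    The raw Gaussian is refined by repeatedly applying the zero-phase
    1-15 Hz band-pass plus baseline subtraction and renormalising the
    extremum near the nominal latency; a 1 Hz high-pass removes a
    substantial share of a slow pulse's peak, and this fixed-point
    iteration yields a shape the chain passes almost unchanged.
    """
    times = t0 + np.arange(n_samples) / fs * 1000.0
    sos = butter(_ANALYSIS_FILTER_ORDER, _ANALYSIS_BAND_HZ, btype="bandpass",
                 fs=fs, output="sos")
    base = (times >= _BASELINE_WINDOW_MS[0]) & (times <= _BASELINE_WINDOW_MS[1])
    near = np.abs(times - latency_ms) <= 2.0 * width_ms
    wave = gaussian_bump(times, latency_ms, width_ms, 1.0)
    for _ in range(_TEMPLATE_REFINE_PASSES):
        ext = wave[near][np.argmax(np.abs(wave[near]))]
        wave = wave / ext
        out = sosfiltfilt(sos, wave)
        if base.any():
            out = out - out[base].mean()
        wave = out
    ext = wave[near][np.argmax(np.abs(wave[near]))]
    wave = wave / ext
    wave.setflags(write=False)
    return wave


def erp_waveform(template: ComponentTemplate, state: str, tone: str,
                 times_ms: np.ndarray, band_limited: bool = False,
                 sampling_rate_hz: float | None = None) -> np.ndarray:
    """Render one component as a single-channel waveform (topography gain 1).

    With ``band_limited=False`` (default) the shape is the analytic
    truncated Gaussian, whose extremum equals the configured amplitude at
    the configured latency exactly.  ``band_limited=True`` returns the
    analysis-chain-invariant shape used inside :func:`simulate_epoch`.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if not (times_ms[0] <= template.latency_ms <= times_ms[-1]):
        raise ValueError(
            f"component latency {template.latency_ms} ms outside epoch window")
    amp = template.amplitude(state, tone)
    if not band_limited:
        return gaussian_bump(times_ms, template.latency_ms, template.width_ms, amp)
    if sampling_rate_hz is None:
        sampling_rate_hz = 1000.0 / float(np.diff(times_ms[:2])[0])
    shape = _band_limited_shape(template.latency_ms, template.width_ms,
                                float(sampling_rate_hz), float(times_ms[0]),
                                len(times_ms))
    return amp * shape


# ---------------------------------------------------------------------------
# noise


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent noise along the last axis (spectral shaping)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0.0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= weights
    out = np.fft.irfft(spec, n=n, axis=-1)
    # analytic variance of the shaped series for unit-variance white input
    w2 = weights**2
    var = (w2[0] + 2.0 * w2[1:-1].sum() + (w2[-1] if n % 2 == 0 else 2.0 * w2[-1])) / n
    return out / math.sqrt(var)


# ---------------------------------------------------------------------------
# epoch / session assembly


def _render_trials(tone_types: Sequence[str], state: str,
                   templates: dict[str, ComponentTemplate],
                   config: GeneratorConfig, rng: np.random.Generator,
                   component_gains: dict[str, float] | None = None) -> np.ndarray:
    """Vectorised signal + noise for a batch of trials in one block.

    Returns an array of shape (n_trials, n_channels, n_samples).
    """
    n_tr = len(tone_types)
    n_ch = len(config.channels)
    n_s = config.n_samples
    times = config.times_ms
    gains = component_gains or {}
    data = np.zeros((n_tr, n_ch, n_s))
    for comp in templates.values():
        shape = erp_waveform(comp, ON_TASK, STANDARD, times, band_limited=True,
                             sampling_rate_hz=config.sampling_rate_hz)
        base_amp = comp.amplitude(ON_TASK, STANDARD)
        unit = shape / base_amp if base_amp != 0.0 else shape
        topo = np.array([comp.topography.get(ch, 0.0) for ch in config.channels])
        amps = np.array([comp.amplitude(state, t) for t in tone_types])
        if config.trial_amplitude_jitter > 0:
            amps = amps * (1.0 + config.trial_amplitude_jitter
                           * rng.standard_normal(n_tr))
        amps = amps * gains.get(comp.name, 1.0)
        data += amps[:, None, None] * topo[None, :, None] * unit[None, None, :]
    if config.noise_pink_scale_uv > 0:
        data += config.noise_pink_scale_uv * pink_noise(
            rng, (n_tr, n_ch, n_s), config.noise_pink_exponent)
    if config.noise_white_sd_uv > 0:
        data += config.noise_white_sd_uv * rng.standard_normal((n_tr, n_ch, n_s))
    return data


def simulate_epoch(state: str, tone: str, templates: dict[str, ComponentTemplate],
                   config: GeneratorConfig, rng: np.random.Generator,
                   block_index: int = 0, trial_index: int = 0,
                   component_gains: dict[str, float] | None = None) -> Epoch:
    """One trial: deterministic band-limited component mix plus noise."""
    for required in ("N1", "P3"):
        if required not in templates:
            raise ValueError(f"template for {required} missing")
    data = _render_trials([tone], state, templates, config, rng,
                          component_gains)[0]
    artifact = bool(rng.random() < config.artifact_probability)
    return Epoch(data, config.times_ms, config.channels, tone,
                 block_index, trial_index, artifact)


def generate_tone_sequence(config: GeneratorConfig, rng: np.random.Generator,
                           mode: str | None = None,
                           n_tones: int | None = None,
                           duration_s: float | None = None
                           ) -> tuple[list[str], np.ndarray]:
    """Tone types with strictly increasing onsets (seconds).

    In ``exact`` mode exactly ``n_tones`` tones are drawn with the global
    standard/target counts fixed to the configured proportions (a random
    permutation).  In ``bernoulli`` mode each tone's type is an
    independent draw, and if ``duration_s`` is given the sequence stops
    before the first onset that would exceed it.  Consecutive onsets are
    separated by the tone duration plus a uniform ITI draw.
    """
    mode = mode or config.tone_mode
    p_std, p_tgt = config.tone_probabilities
    if mode == "exact":
        total = n_tones if n_tones is not None else config.total_tones
        if total < 1:
            raise ValueError("n_tones must be positive")
        n_std = int(round(total * p_std))
        types = np.array([STANDARD] * n_std + [TARGET] * (total - n_std))
        rng.shuffle(types)
        types = list(types)
    elif mode == "bernoulli":
        if duration_s is None and n_tones is None:
            raise ValueError("bernoulli mode needs n_tones or duration_s")
        max_n = n_tones if n_tones is not None else 10**9
        types = []
    else:
        raise ValueError(f"unknown tone mode {mode!r}")

    gap_base_s = config.tone_duration_ms / 1000.0
    iti_lo, iti_hi = (v / 1000.0 for v in config.iti_range_ms)
    onsets: list[float] = []
    t = 0.0
    if mode == "exact":
        for _ in types:
            onsets.append(t)
            t += gap_base_s + rng.uniform(iti_lo, iti_hi)
    else:
        while len(types) < max_n:
            if duration_s is not None and t + gap_base_s > duration_s and types:
                break
            types.append(TARGET if rng.random() < p_tgt else STANDARD)
            onsets.append(t)
            t += gap_base_s + rng.uniform(iti_lo, iti_hi)
    return list(types), np.asarray(onsets)


def _draw_mw_rate(config: GeneratorConfig, rng: np.random.Generator) -> float:
    lo, hi = config.mw_rate_range
    if lo == hi:
        return lo
    m, sd = config.mw_rate_mean, config.mw_rate_sd
    if sd <= 0:
        return min(max(m, lo), hi)
    var = sd * sd
    nu = m * (1.0 - m) / var - 1.0
    if nu <= 0:
        raise ValueError("mw_rate_sd too large for a Beta distribution")
    a, b = m * nu, (1.0 - m) * nu
    for _ in range(1000):
        draw = rng.beta(a, b)
        if lo <= draw <= hi:
            return float(draw)
    return float(min(max(rng.beta(a, b), lo), hi))


def generate_subject(config: GeneratorConfig, subject_id: str,
                     rng: np.random.Generator,
                     templates: dict[str, ComponentTemplate] | None = None
                     ) -> SubjectSession:
    """Simulate one participant: blocks of epochs, each ending in a probe.

    Block durations are uniform on the configured range.  In exact mode
    the session-wide tone sequence has exactly the configured
    standard/target counts, apportioned to blocks in proportion to their
    durations (largest-remainder rounding); in Bernoulli mode each block
    is filled until its duration is reached.  Each block's attention
    state is a Bernoulli draw at the subject's mind-wandering rate.
    """
    templates = templates or default_templates(config)
    mw_rate = _draw_mw_rate(config, rng)
    gains = {name: max(0.2, 1.0 + config.subject_gain_sd * rng.standard_normal())
             for name in templates}
    rt_offset = config.rt_subject_sd_ms * rng.standard_normal()

    durations = rng.uniform(*config.block_duration_range_s, size=config.n_blocks)
    block_tone_lists: list[tuple[list[str], np.ndarray]] = []
    if config.tone_mode == "exact":
        types, _ = generate_tone_sequence(config, rng, mode="exact")
        # apportion tones to blocks proportionally to duration
        quota = config.total_tones * durations / durations.sum()
        counts = np.floor(quota).astype(int)
        for i in np.argsort(quota - counts)[::-1][: config.total_tones - counts.sum()]:
            counts[i] += 1
        pos = 0
        gap_base_s = config.tone_duration_ms / 1000.0
        iti_lo, iti_hi = (v / 1000.0 for v in config.iti_range_ms)
        for c in counts:
            blk_types = types[pos: pos + c]
            pos += c
            gaps = gap_base_s + rng.uniform(iti_lo, iti_hi, size=len(blk_types))
            onsets = np.concatenate(([0.0], np.cumsum(gaps[:-1])))
            block_tone_lists.append((blk_types, onsets))
    else:
        for d in durations:
            block_tone_lists.append(
                generate_tone_sequence(config, rng, mode="bernoulli", duration_s=d))

    blocks: list[Block] = []
    for b_idx, ((blk_types, onsets), dur) in enumerate(zip(block_tone_lists, durations)):
        state = MIND_WANDERING if rng.random() < mw_rate else ON_TASK
        data = _render_trials(blk_types, state, templates, config, rng, gains)
        artifacts = rng.random(len(blk_types)) < config.artifact_probability
        trials = [
            Epoch(data[i], config.times_ms, config.channels, blk_types[i],
                  b_idx, i, bool(artifacts[i]))
            for i in range(len(blk_types))
        ]
        rt_mean = (config.rt_mean_mw_ms if state == MIND_WANDERING
                   else config.rt_mean_on_task_ms) + rt_offset
        rts = [(i, float(max(150.0, rt_mean + config.rt_trial_sd_ms
                             * rng.standard_normal())))
               for i, t in enumerate(blk_types) if t == TARGET]
        blocks.append(Block(trials, state, float(dur), rts,
                            np.asarray(onsets)))

    true_params = {
        "mw_rate": mw_rate,
        "component_gains": gains,
        "mw_attenuation": config.mw_attenuation,
        "rt_offset_ms": rt_offset,
    }
    return SubjectSession(subject_id, blocks, config.channels,
                          config.sampling_rate_hz, true_params)


def generate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | int | None = None,
                    templates: dict[str, ComponentTemplate] | None = None
                    ) -> list[SubjectSession]:
    """Independent sessions for ``config.n_subjects`` participants."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _as_rng(rng if rng is not None else config.seed)
    return [
        generate_subject(config, f"sub-{i + 1:02d}", rng, templates)
        for i in range(config.n_subjects)
    ]


def iter_cohort(config: GeneratorConfig,
                rng: np.random.Generator | int | None = None,
                templates: dict[str, ComponentTemplate] | None = None):
    """Yield sessions one at a time (memory-friendly for large cohorts)."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _as_rng(rng if rng is not None else config.seed)
    for i in range(config.n_subjects):
        yield generate_subject(config, f"sub-{i + 1:02d}", rng, templates)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
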