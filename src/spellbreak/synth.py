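"""Synthetic EEG session generators for the P300 and SSVEP paradigms.

These generators emulate the statistical structure the victim decoders
rely on, so the full attack pipeline can be exercised without any
recorded data.

P300 oddball sessions
    A continuous multichannel recording containing, per character trial,
    ``n_repeats`` cycles of 12 row/column intensifications in random
    order (stimulus onset asynchrony 175 ms: 100 ms flash + 75 ms blank).
    Every intensification of the attended character's row or column adds
    a positive event-related deflection -- a raised-cosine bump centred
    ``erp_latency_ms`` after flash onset, projected through a fixed
    spatial pattern -- on top of spatially mixed 1/f background noise.
    The finished recording is z-normalized per channel.

SSVEP sessions
    Blocked single trials, one per stimulation frequency and block.  Each
    trial holds background noise plus, from ``onset_delay_s`` after the
    stimulus onset, a sum of harmonics of the trial's flicker frequency
    projected through a posterior channel profile, scaled to a target
    signal-to-noise ratio and z-normalized per channel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import chars
from ._rng import TAG_MIXING, TAG_P300_TEST, TAG_P300_TRAIN, TAG_SSVEP, derive_rng

__all__ = [
    "P300SimConfig",
    "SSVEPSimConfig",
    "P300Session",
    "SSVEPSession",
    "SSVEPTrial",
    "make_p300_session",
    "make_ssvep_session",
]


# ---------------------------------------------------------------------------
# configuration


def _default_spatial_pattern(n_channels: int) -> np.ndarray:
    """Smooth centro-parietal-like unit-norm profile over the montage."""
    x = np.linspace(-1.0, 1.0, n_channels)
    p = np.exp(-((x - 0.15) ** 2) / 0.18)
    return p / np.linalg.norm(p)


@dataclass(frozen=True)
class P300SimConfig:
    """Study conditions for a simulated P300 speller subject."""

    n_channels: int = 16
    fs: float = 240.0
    n_train_chars: int = 85
    n_test_chars: int = 100
    n_repeats: int = 15
    flash_ms: float = 100.0
    blank_ms: float = 75.0
    erp_latency_ms: float = 300.0
    erp_width_ms: float = 200.0
    erp_amplitude: float = 0.7
    inter_char_gap_ms: float = 0.0
    noise_model: str = "one_over_f"
    # power-spectral exponent of the background; the public P300 recordings
    # are band-passed 0.1-40 Hz, which flattens the spectrum, so 1 is used
    noise_exponent: float = 1.0
    spatial_pattern: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if min(self.flash_ms, self.blank_ms, self.erp_width_ms) <= 0:
            raise ValueError("durations must be positive")
        if abs(self.flash_ms + self.blank_ms - 175.0) > 1e-9:
            raise ValueError("flash_ms + blank_ms must equal the 175 ms SOA")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_model not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.spatial_pattern is not None:
            p = np.asarray(self.spatial_pattern, float)
            if p.shape != (self.n_channels,):
                raise ValueError("spatial_pattern must have one entry per channel")
            if abs(np.linalg.norm(p) - 1.0) > 1e-8:
                raise ValueError("spatial_pattern must have unit Euclidean norm")

    @property
    def soa_ms(self) -> float:
        return self.flash_ms + self.blank_ms

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa_ms / 1000.0 * self.fs))

    def pattern(self) -> np.ndarray:
        if self.spatial_pattern is not None:
            return np.asarray(self.spatial_pattern, float)
        return _default_spatial_pattern(self.n_channels)


@dataclass(frozen=True)
class SSVEPSimConfig:
    """Study conditions for a simulated SSVEP speller subject."""

    n_channels: int = 9
    fs: float = 250.0
    n_blocks: int = 6
    freqs: tuple[float, ...] = tuple(np.round(chars.ssvep_frequencies(), 10))
    onset_delay_s: float = 0.14
    trial_len_s: float = 6.0
    pre_stim_s: float = 0.5
    stim_len_s: float = 5.0
    n_harmonics: int = 3
    harmonic_decay: float = 1.0  # amplitude of harmonic h scales as decay / h
    snr_db: float = -26.0
    noise_model: str = "one_over_f"
    # raw (unfiltered) EEG falls off roughly as 1/f^2; most trial energy
    # then sits below the decoder's 7 Hz passband edge, as in recordings
    noise_exponent: float = 2.0
    # flat broadband floor (sensor/EMG noise) as a fraction of total power
    noise_white_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if f.size > 1 and not np.allclose(np.diff(f), 0.2, atol=1e-9):
            raise ValueError("freqs must be spaced 0.2 Hz apart")
        if not (0.13 - 1e-12 <= self.onset_delay_s <= 0.14 + 1e-12):
            raise ValueError("onset_delay_s must lie in [0.13, 0.14]")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.fs))

    @property
    def onset_sample(self) -> int:
        return int(round(self.pre_stim_s * self.fs))


# ---------------------------------------------------------------------------
# session containers


@dataclass
class P300Event:
    onset_sample: int
    stimulus_id: int  # 1..6 rows, 7..12 columns
    repeat_index: int
    trial_index: int


@dataclass
class P300TrialInfo:
    trial_index: int
    target_row: int  # 1..6
    target_col: int  # 1..6
    target_char: str


@dataclass
class P300Session:
    """Continuous recording plus intensification schedule and targets."""

    signal: np.ndarray  # (n_channels, n_samples), z-normalized per channel
    events: list[P300Event]
    trials: list[P300TrialInfo]
    fs: float
    split: str
    n_repeats: int

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def trial_events(self, trial_index: int, n_repeats: int | None = None) -> list[P300Event]:
        evs = [e for e in self.events if e.trial_index == trial_index]
        if n_repeats is not None:
            if n_repeats > max(e.repeat_index for e in evs) + 1:
                raise ValueError("n_repeats exceeds available repeats")
            evs = [e for e in evs if e.repeat_index < n_repeats]
        return evs

    def validate(self) -> None:
        """Re-check structural invariants (used after deserialization)."""
        seen: dict[tuple[int, int], list[int]] = {}
        for e in self.events:
            seen.setdefault((e.trial_index, e.repeat_index), []).append(e.stimulus_id)
        for (t, r), ids in seen.items():
            if sorted(ids) != list(range(1, 13)):
                raise ValueError(
                    f"trial {t} repeat {r}: stimulus ids are not a permutation of 1..12"
                )
        mu = self.signal.mean(axis=1)
        sd = self.signal.std(axis=1)
        if np.max(np.abs(mu)) > 1e-6 or np.max(np.abs(sd - 1.0)) > 1e-6:
            raise ValueError("signal channels are not z-normalized")


@dataclass
class SSVEPTrial:
    signal: np.ndarray  # (n_channels, n_samples), z-normalized per channel
    freq: float
    char: str
    onset_sample: int
    fs: float


@dataclass
class SSVEPSession:
    blocks: list[list[SSVEPTrial]]
    fs: float

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def validate(self) -> None:
        for bi, block in enumerate(self.blocks):
            fr = sorted(round(t.freq, 10) for t in block)
            if len(set(fr)) != len(block):
                raise ValueError(f"block {bi}: duplicate stimulation frequency")


# ---------------------------------------------------------------------------
# noise


def _background_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    model: str,
    exponent: float = 1.0,
    fs: float = 1.0,
    f_min_hz: float = 0.5,
    mixing: np.ndarray | None = None,
    white_fraction: float = 0.0,
) -> np.ndarray:
    """Unit-scale background noise, optionally 1/f^exponent-shaped and
    spatially mixed.

    ``exponent`` is the power-spectral exponent (EEG spectra typically
    fall off with exponents between 1 and 2); the shaping is flattened
    below ``f_min_hz`` so the lowest bins do not dominate.
    ``white_fraction`` adds a flat broadband floor (sensor/EMG noise)
    carrying that fraction of the total power, so high-frequency bands
    are not unrealistically silent.  ``mixing`` is the subject's fixed
    full-rank channel-mixing matrix; it is a property of the simulated
    head, shared by all recordings of that subject, so covariance
    structure transfers across splits.
    """
    if model == "white":
        return rng.standard_normal((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(f)  # no DC drift
    f_eff = np.maximum(f, f_min_hz)
    shaping[1:] = f_eff[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    if white_fraction > 0.0:
        floor = rng.standard_normal((n_channels, n_samples))
        noise = np.sqrt(1.0 - white_fraction) * noise + np.sqrt(white_fraction) * floor
    if mixing is not None:
        noise = mixing @ noise
    return noise / noise.std(axis=1, keepdims=True)


def _subject_mixing(seed: int, n_channels: int) -> np.ndarray:
    """Full-rank channel-mixing matrix, fixed per subject (seed)."""
    rng = derive_rng(seed, TAG_MIXING)
    return np.eye(n_channels) + 0.3 * rng.standard_normal((n_channels, n_channels))


def _znorm_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    return x / x.std(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# P300


def _raised_cosine(width_samples: int) -> np.ndarray:
    """Raised-cosine bump of unit peak amplitude, zero at both ends."""
    t = np.arange(width_samples)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 1) / (width_samples + 1)))


def make_p300_session(config: P300SimConfig, split: str) -> P300Session:
    """Simulate one continuous P300 oddball session.

    Deterministic given ``config.seed`` and ``split``; the train and test
    splits use independent sub-streams of the same master seed.
    """
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    tag = TAG_P300_TRAIN if split == "train" else TAG_P300_TEST
    rng = derive_rng(config.seed, tag)

    n_chars = config.n_train_chars if split == "train" else config.n_test_chars
    soa = config.soa_samples
    gap = int(round(config.inter_char_gap_ms / 1000.0 * config.fs))
    trial_len = 12 * config.n_repeats * soa + gap
    epoch_len = int(round(0.600 * config.fs))
    n_samples = n_chars * trial_len + epoch_len  # tail so the last epoch fits

    events: list[P300Event] = []
    trials: list[P300TrialInfo] = []
    target_chars = rng.choice(list(chars.P300_CHARS), size=n_chars)
    for t in range(n_chars):
        char = str(target_chars[t])
        row, col = chars.p300_char_position(char)
        trials.append(P300TrialInfo(t, row, col, char))
        start = t * trial_len
        for r in range(config.n_repeats):
            order = rng.permutation(12) + 1
            for k, sid in enumerate(order):
                onset = start + (r * 12 + k) * soa
                events.append(P300Event(onset, int(sid), r, t))

    mixing = _subject_mixing(config.seed, config.n_channels)
    signal = _background_noise(
        rng, config.n_channels, n_samples, config.noise_model,
        config.noise_exponent, config.fs, mixing=mixing,
    )

    if config.erp_amplitude != 0.0:
        width = int(round(config.erp_width_ms / 1000.0 * config.fs))
        latency = int(round(config.erp_latency_ms / 1000.0 * config.fs))
        bump = config.erp_amplitude * _raised_cosine(width)
        pattern = config.pattern()
        half = width // 2
        by_trial = {tr.trial_index: (tr.target_row, 6 + tr.target_col) for tr in trials}
        for e in events:
            if e.stimulus_id in by_trial[e.trial_index]:
                lo = e.onset_sample + latency - half
                hi = lo + width
                b0, b1 = max(lo, 0), min(hi, n_samples)
                signal[:, b0:b1] += np.outer(pattern, bump[b0 - lo : b1 - lo])

    signal = _znorm_rows(signal)
    return P300Session(signal, events, trials, config.fs, split, config.n_repeats)


# ---------------------------------------------------------------------------
# SSVEP


def _ssvep_waveform(
    config: SSVEPSimConfig, freq: float, phases: np.ndarray, n_active: int
) -> np.ndarray:
    """Sum of harmonics (unit base amplitude) over the stimulation span."""
    t = np.arange(n_active) / config.fs
    wave = np.zeros(n_active)
    for h in range(1, config.n_harmonics + 1):
        if h * freq >= config.fs / 2.0:
            # harmonic above Nyquist: drop rather than alias
            logging.getLogger(__name__).warning(
                "dropping harmonic %d of %.1f Hz (above Nyquist)", h, freq
            )
            continue
        amp = config.harmonic_decay / h
        wave += amp * np.sin(2.0 * np.pi * h * freq * t + phases[h - 1])
    return wave


def make_ssvep_session(config: SSVEPSimConfig) -> SSVEPSession:
    """Simulate one blocked SSVEP session (``n_blocks`` x 40 trials).

    Within each block every stimulation frequency occurs exactly once, in
    random order.  ``snr_db = inf`` disables the background noise.
    """
    rng = derive_rng(config.seed, TAG_SSVEP)
    cmap = chars.ssvep_char_map()
    n_samples = config.n_samples
    onset = config.onset_sample
    delay = int(round(config.onset_delay_s * config.fs))
    stim_start = onset + delay
    stim_len = min(int(round(config.stim_len_s * config.fs)) - delay, n_samples - stim_start)

    pattern = _default_spatial_pattern(config.n_channels)
    mixing = _subject_mixing(config.seed, config.n_channels)
    noiseless = math.isinf(config.snr_db)

    blocks: list[list[SSVEPTrial]] = []
    for _b in range(config.n_blocks):
        order = rng.permutation(len(config.freqs))
        block: list[SSVEPTrial] = []
        for idx in order:
            freq = float(config.freqs[idx])
            phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_harmonics)
            wave = _ssvep_waveform(config, freq, phases, stim_len)
            comp = np.outer(pattern, wave)  # (C, stim_len)

            if noiseless:
                sig = np.zeros((config.n_channels, n_samples))
                sig[:, stim_start : stim_start + stim_len] = comp
            else:
                noise = _background_noise(
                    rng, config.n_channels, n_samples, config.noise_model,
                    config.noise_exponent, config.fs, mixing=mixing,
                    white_fraction=config.noise_white_fraction,
                )
                # scale the evoked component to the requested SNR, measured
                # as total evoked power over total noise power in the
                # stimulation span
                p_noise = np.mean(noise[:, stim_start : stim_start + stim_len] ** 2)
                p_sig = np.mean(comp**2)
                scale = np.sqrt(10.0 ** (config.snr_db / 10.0) * p_noise / p_sig)
                sig = noise
                sig[:, stim_start : stim_start + stim_len] += scale * comp
                sig = _znorm_rows(sig)
            block.append(SSVEPTrial(sig, freq, cmap[round(freq, 10)], onset, config.fs))
        blocks.append(block)
    return SSVEPSession(blocks, config.fs)
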