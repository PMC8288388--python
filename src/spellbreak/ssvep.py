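"""The SSVEP speller victim model: CCA frequency recognition.

An EEG window ``X`` (channels x samples) is compared against a bank of
sine/cosine reference signals, one per candidate stimulation frequency
``f``; the decoded frequency maximizes the largest canonical correlation

    rho(X, Y_f) = sqrt(lambda_max(S)),
    S = (X X^T)^-1 X Y_f^T (Y_f Y_f^T)^-1 Y_f X^T,

with rows of X and Y_f z-normalized first and both Gram inverses ridge
stabilized.  Preprocessing follows the usual SSVEP recipe: posterior
channel subset, zero-phase 7-90 Hz band-pass, and a [0.13, 1.38] s window
after stimulus onset (the steady-state response starts with a 130-140 ms
cortical delay).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .chars import ssvep_char_map, ssvep_frequencies
from .synth import SSVEPTrial

__all__ = [
    "ReferenceSignal",
    "FrequencySet",
    "SSVEPPreprocConfig",
    "build_reference",
    "cca_rho",
    "preprocess",
    "window_bounds",
    "decode_frequency",
]

log = logging.getLogger(__name__)

RIDGE_EPS = 1e-8


@dataclass(frozen=True)
class ReferenceSignal:
    """Harmonic sine/cosine reference bank for one stimulation frequency.

    Row ``c`` (1-based), sample ``n`` (1-based):
    ``sin((c+1) pi f/fs n)`` for odd ``c``, ``cos(c pi f/fs n)`` for even
    ``c`` -- i.e. rows alternate sine/cosine of harmonics 1..n_harmonics.
    """

    y: np.ndarray  # (2*n_harmonics, n_samples)
    freq: float
    fs: float
    n_harmonics: int


def build_reference(
    freq: float, fs: float, n_samples: int, n_harmonics: int = 5
) -> ReferenceSignal:
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    n = np.arange(1, n_samples + 1)
    rows = []
    for c in range(1, 2 * n_harmonics + 1):
        if c % 2 == 1:
            rows.append(np.sin((c + 1) * np.pi * freq / fs * n))
        else:
            rows.append(np.cos(c * np.pi * freq / fs * n))
    return ReferenceSignal(np.array(rows), freq, fs, n_harmonics)


@dataclass(frozen=True)
class FrequencySet:
    """Candidate stimulation frequencies and their character map."""

    freqs: tuple[float, ...] = tuple(np.round(ssvep_frequencies(), 10))
    char_map: dict[float, str] | None = None

    def __post_init__(self) -> None:
        if len(self.freqs) == 0:
            raise ValueError("frequency set must be non-empty")

    def char_for(self, freq: float) -> str:
        cmap = ssvep_char_map() if self.char_map is None else self.char_map
        return cmap[round(float(freq), 10)]


@dataclass(frozen=True)
class SSVEPPreprocConfig:
    band: tuple[float, float] = (7.0, 90.0)
    filter_order: int = 4
    window_s: tuple[float, float] = (0.13, 1.38)
    channels: tuple[int, ...] | None = None  # None: keep all


def window_bounds(window_s: tuple[float, float], onset_sample: int, fs: float) -> tuple[int, int]:
    """Half-open sample window; floor at both ends (bit-reproducible)."""
    lo = onset_sample + int(np.floor(window_s[0] * fs))
    hi = onset_sample + int(np.floor(window_s[1] * fs))
    return lo, hi


def window_length(fs: float, window_s: tuple[float, float] = (0.13, 1.38)) -> int:
    lo, hi = window_bounds(window_s, 0, fs)
    return hi - lo


def preprocess(trial: SSVEPTrial, config: SSVEPPreprocConfig = SSVEPPreprocConfig()) -> np.ndarray:
    """Channel subset -> zero-phase Butterworth band-pass -> onset window."""
    sig = trial.signal
    if config.channels is not None:
        sig = sig[list(config.channels)]
    sos = scipy.signal.butter(
        config.filter_order, config.band, btype="bandpass", fs=trial.fs, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, sig, axis=1)
    lo, hi = window_bounds(config.window_s, trial.onset_sample, trial.fs)
    if lo < 0 or hi > sig.shape[1]:
        raise ValueError("decoding window exceeds trial bounds")
    return filtered[:, lo:hi]


# ---------------------------------------------------------------------------
# CCA


def _znorm_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ridge_gram(x: np.ndarray) -> np.ndarray:
    g = x @ x.T
    m = g.shape[0]
    tr = np.trace(g)
    if tr == 0:
        tr = 1.0
    return g + RIDGE_EPS * tr / m * np.eye(m)


def _inv_sqrt(g: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(g)
    w = np.maximum(w, np.finfo(float).tiny)
    return (u / np.sqrt(w)) @ u.T


def cca_rho(x: np.ndarray, y: np.ndarray | ReferenceSignal) -> float:
    """Largest canonical correlation between ``x`` and a reference.

    Computed as the largest singular value of
    ``(XX^T)^-1/2 X Y^T (YY^T)^-1/2`` after per-row z-normalization,
    which equals the square root of the largest eigenvalue of ``S``.
    Clipped to [0, 1].
    """
    if isinstance(y, ReferenceSignal):
        y = y.y
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("X and Y_f must have the same number of samples")
    xz = _znorm_rows(x)
    yz = _znorm_rows(y)
    a = _inv_sqrt(_ridge_gram(xz))
    b = _inv_sqrt(_ridge_gram(yz))
    s = np.linalg.svd(a @ xz @ yz.T @ b, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


class _ReferenceBank:
    """Pre-whitened reference bank: rho = sigma_max(A^-1/2 X B_f^T)."""

    def __init__(self, freqs: tuple[float, ...], fs: float, n_samples: int, n_harmonics: int):
        self.freqs = freqs
        self.b = []
        for f in freqs:
            yz = _znorm_rows(build_reference(f, fs, n_samples, n_harmonics).y)
            self.b.append(_inv_sqrt(_ridge_gram(yz)) @ yz)

    def rhos(self, x: np.ndarray) -> np.ndarray:
        xz = _znorm_rows(x)
        a = _inv_sqrt(_ridge_gram(xz))
        ax = a @ xz
        return np.array(
            [np.clip(np.linalg.svd(ax @ bf.T, compute_uv=False)[0], 0.0, 1.0) for bf in self.b]
        )


_bank_cache: dict[tuple, _ReferenceBank] = {}


def _get_bank(
    freqs: tuple[float, ...], fs: float, n_samples: int, n_harmonics: int
) -> _ReferenceBank:
    key = (freqs, fs, n_samples, n_harmonics)
    if key not in _bank_cache:
        _bank_cache[key] = _ReferenceBank(freqs, fs, n_samples, n_harmonics)
    return _bank_cache[key]


def decode_frequency(
    x: np.ndarray,
    freq_set: FrequencySet = FrequencySet(),
    fs: float = 250.0,
    n_harmonics: int = 5,
) -> tuple[float, str]:
    """Maximum-correlation frequency and character for a preprocessed window.

    Ties break toward the lowest frequency (argmax keeps the first max).
    """
    bank = _get_bank(tuple(freq_set.freqs), fs, x.shape[1], n_harmonics)
    rhos = bank.rhos(np.asarray(x, float))
    f_star = float(freq_set.freqs[int(np.argmax(rhos))])
    return f_star, freq_set.char_for(f_star)


def decode_trial(
    trial: SSVEPTrial,
    freq_set: FrequencySet = FrequencySet(),
    preproc: SSVEPPreprocConfig = SSVEPPreprocConfig(),
    n_harmonics: int = 5,
) -> tuple[float, str]:
    """Preprocess a raw trial and decode its stimulation frequency."""
    return decode_frequency(preprocess(trial, preproc), freq_set, trial.fs, n_harmonics)
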