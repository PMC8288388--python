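"""Adversarial perturbation template for the P300 speller.

The attack builds one fixed short multichannel waveform from the victim
model and the training nontarget epochs: the input-gradient directions
that push nontarget epochs toward the target class are normalized per
epoch, summed, band-pass filtered to 0.1-15 Hz, truncated to 350 ms (two
intensification periods) and scaled so each channel has L2 norm epsilon.
The template is then fixed; at attack time it is added to the continuous
signal at the onsets of the attacker character's row and column
intensifications, so the attack is causal -- nothing about the test
trial needs to be known in advance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import p300
from ._rng import TAG_ATTACK, derive_rng
from .chars import p300_stimulus_ids
from .synth import P300Session

__all__ = [
    "P300AttackConfig",
    "P300Template",
    "build_template",
    "gaussian_template",
    "inject",
    "inject_session",
    "attack_session",
]


@dataclass(frozen=True)
class P300AttackConfig:
    band: tuple[float, float] = (0.1, 15.0)
    filter_order: int = 4
    template_len_ms: float = 350.0
    epsilon: float = 0.5

    def template_len(self, fs: float) -> int:
        return int(round(self.template_len_ms / 1000.0 * fs))


@dataclass
class P300Template:
    """Fixed perturbation waveform, one channel per row."""

    p: np.ndarray  # (n_channels, round(0.350 * fs))
    fs: float
    config: P300AttackConfig
    kind: str = "adversarial"  # or "gaussian"


def _postprocess(direction: np.ndarray, fs: float, config: P300AttackConfig) -> np.ndarray:
    """Shared post-processing: band-pass, truncate to 350 ms, normalize.

    Zero-phase filtering with reflect padding (sosfiltfilt defaults);
    per-channel L2 norm is set to 1 and then scaled by epsilon.
    """
    sos = scipy.signal.butter(
        config.filter_order, config.band, btype="bandpass", fs=fs, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, direction, axis=1)
    trunc = filtered[:, : config.template_len(fs)]
    norms = np.linalg.norm(trunc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return config.epsilon * trunc / norms


def build_template(
    model: p300.P300VictimModel,
    train_session: P300Session,
    config: P300AttackConfig = P300AttackConfig(),
) -> P300Template:
    """Construct the adversarial template from training nontarget epochs.

    Per nontarget epoch the gradient of the cross-entropy loss toward the
    flipped (target) label is taken; the loss-descent direction -- the one
    that raises the target probability -- is normalized by its Frobenius
    norm and the directions are summed.  Epochs with (numerically) zero
    gradient are skipped.
    """
    epochs = p300.extract_epochs(train_session)
    nt = [e.data for e in epochs if e.label == 0]
    if not nt:
        raise ValueError("no nontarget epochs in the training session")
    data = np.stack(nt)
    # descent direction of J(X, 1): -grad raises the target probability
    grads = -p300.loss_gradient(model, data, 1)
    norms = np.linalg.norm(grads, axis=(1, 2))
    keep = norms > 0
    direction = (grads[keep] / norms[keep, None, None]).sum(axis=0)
    return P300Template(_postprocess(direction, model.fs, config), model.fs, config)


def gaussian_template(
    model: p300.P300VictimModel,
    config: P300AttackConfig = P300AttackConfig(),
    seed: int = 0,
) -> P300Template:
    """Energy-matched control: the same post-processing applied to
    standard Gaussian noise instead of the summed gradient direction."""
    rng = derive_rng(seed, TAG_ATTACK)
    noise = rng.standard_normal((model.n_channels, model.epoch_len))
    return P300Template(_postprocess(noise, model.fs, config), model.fs, config, "gaussian")


# ---------------------------------------------------------------------------
# injection


def injection_onsets(
    session: P300Session, attacker_char: str, delay_samples: int = 0
) -> list[int]:
    """Start samples of every template injection for ``attacker_char``."""
    row_id, col_id = p300_stimulus_ids(attacker_char)
    return [
        e.onset_sample + delay_samples
        for e in session.events
        if e.stimulus_id in (row_id, col_id)
    ]


def inject(
    signal: np.ndarray,
    onsets: list[int],
    template: P300Template,
) -> np.ndarray:
    """Add the template at each onset; overlapping additions sum.

    A template extending past the end of the recording is clipped with a
    warning.  Returns a new array; samples outside every injection window
    are bit-identical to the input.
    """
    out = signal.copy()
    n = signal.shape[1]
    tlen = template.p.shape[1]
    for o in onsets:
        if o < 0 or o >= n:
            continue
        hi = min(o + tlen, n)
        if hi < o + tlen:
            warnings.warn("template clipped at the end of the recording")
        out[:, o:hi] += template.p[:, : hi - o]
    return out


def inject_session(
    session: P300Session,
    template: P300Template,
    attacker_char: str,
    delay_ms: float = 0.0,
) -> P300Session:
    """Perturbed copy of the session (signal replaced, schedule shared)."""
    delay = int(round(delay_ms / 1000.0 * session.fs))
    onsets = injection_onsets(session, attacker_char, delay)
    perturbed = inject(session.signal, onsets, template)
    return P300Session(
        perturbed, session.events, session.trials, session.fs, session.split, session.n_repeats
    )


# ---------------------------------------------------------------------------
# whole-session attack


def _sprs(
    session: P300Session, perturbed: P300Session, template: P300Template, onsets: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (period SPR, trial SPR) in dB against the clean signal."""
    from .evaluate import spr  # local import to avoid a cycle

    diff = perturbed.signal - session.signal
    tlen = template.p.shape[1]
    n = session.signal.shape[1]
    period_db, trial_db = [], []
    for tr in session.trials:
        evs = session.trial_events(tr.trial_index)
        lo = min(e.onset_sample for e in evs)
        hi = min(max(e.onset_sample for e in evs) + tlen, n)
        mask = np.zeros(hi - lo, bool)
        for o in onsets:
            if lo <= o < hi:
                mask[o - lo : min(o + tlen, hi) - lo] = True
        sl_sig = session.signal[:, lo:hi]
        sl_diff = diff[:, lo:hi]
        period_db.append(spr(sl_sig[:, mask], sl_diff[:, mask]))
        trial_db.append(spr(sl_sig, sl_diff))
    return np.array(period_db), np.array(trial_db)


def attack_session(
    model: p300.P300VictimModel,
    session: P300Session,
    template: P300Template,
    attacker_char: str,
    n_repeats: int = 15,
    delay_ms: float = 0.0,
    with_spr: bool = False,
):
    """Inject the template per the attacker schedule and decode all trials.

    Returns the decoded characters, and with ``with_spr`` also the
    per-trial period/trial signal-to-perturbation ratios in dB.
    """
    perturbed = inject_session(session, template, attacker_char, delay_ms)
    decoded = p300.decode_session(model, perturbed, n_repeats)
    if not with_spr:
        return decoded
    delay = int(round(delay_ms / 1000.0 * session.fs))
    onsets = injection_onsets(session, attacker_char, delay)
    period_db, trial_db = _sprs(session, perturbed, template, onsets)
    return decoded, period_db, trial_db
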