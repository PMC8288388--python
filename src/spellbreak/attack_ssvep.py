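"""Adversarial perturbation template for the SSVEP speller.

A CCA decoder has no fixed parameters to attack -- the canonical weights
are re-fit on every trial -- so the template is optimized directly: find
a band-limited waveform ``delta = filt(r)`` that, added to any trial,
makes the maximum canonical correlation with the attacker frequency's
reference bank dominate.  The surrogate objective replaces the largest
eigenvalue with the trace of the CCA matrix ``S``:

    min_r  - sum_{X in D} tr(S(X + filt(r), Y_fhat)) + alpha ||filt(r)||_F

where ``D`` is the first (training) block and ``filt`` keeps only the
7-90 Hz components (an exact DFT-mask projection, so the template
survives the decoder's band-pass filtering unchanged).  Plain gradient
descent with step halving updates ``r``; iterations stop once the mean
signal-to-perturbation ratio over the training block drops below the
stopping threshold (25 dB), which pins the template's final energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ssvep
from ._rng import TAG_ATTACK, TAG_BASELINE, derive_rng
from .evaluate import spr
from .synth import SSVEPSession, SSVEPTrial

__all__ = [
    "SSVEPAttackConfig",
    "SSVEPTemplate",
    "filt",
    "trace_objective",
    "trace_objective_grad",
    "optimize_template",
    "inject",
    "noise_baselines",
]


@dataclass(frozen=True)
class SSVEPAttackConfig:
    alpha: float = 0.05
    spr_stop_db: float = 25.0
    step_size: float = 0.05
    max_iters: int = 5000
    band: tuple[float, float] = (7.0, 90.0)
    n_harmonics: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spr_stop_db <= 0:
            raise ValueError("spr_stop_db must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class SSVEPTemplate:
    delta: np.ndarray  # (n_channels, n_samples) band-limited waveform
    attacker_freq: float
    raw: np.ndarray  # the optimized parameter r (delta = filt(r))
    converged: bool
    n_iters: int
    train_spr_db: float
    objective_log: np.ndarray


def filt(r: np.ndarray, fs: float = 250.0, band: tuple[float, float] = (7.0, 90.0)) -> np.ndarray:
    """Exact band-limiting projection: zero all DFT bins outside ``band``.

    Linear, idempotent and self-adjoint -- the properties the optimizer
    relies on.
    """
    r = np.atleast_2d(np.asarray(r, float))
    spec = np.fft.rfft(r, axis=1)
    f = np.fft.rfftfreq(r.shape[1], d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    return np.fft.irfft(spec * mask, n=r.shape[1], axis=1)


def raw_window_energy(
    trial: SSVEPTrial, window_s: tuple[float, float] = (0.13, 1.38)
) -> float:
    """Energy of the raw (unfiltered) trial over the decoding window."""
    lo, hi = ssvep.window_bounds(window_s, trial.onset_sample, trial.fs)
    return float(np.sum(trial.signal[:, lo:hi] ** 2))


def template_spr_db(
    trial: SSVEPTrial, template: "SSVEPTemplate",
    window_s: tuple[float, float] = (0.13, 1.38),
) -> float:
    """Trial SPR in dB of the template against the raw decoding window."""
    e = float(np.sum(template.delta**2))
    if e == 0:
        return float("inf")
    return 10.0 * np.log10(raw_window_energy(trial, window_s) / e)


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def _ridge_inv(g: np.ndarray) -> np.ndarray:
    m = g.shape[0]
    tr = np.trace(g)
    if tr == 0:
        tr = 1.0
    return np.linalg.inv(g + ssvep.RIDGE_EPS * tr / m * np.eye(m))


def _ref_projection(f_hat: float, fs: float, n_samples: int, n_harmonics: int) -> np.ndarray:
    """K_Y = Y^T (YY^T)^-1 Y for the z-normalized attacker reference."""
    y = ssvep.build_reference(f_hat, fs, n_samples, n_harmonics).y
    y = y - y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    y = y / sd
    return y.T @ _ridge_inv(y @ y.T) @ y


def trace_objective(
    xs: np.ndarray, delta: np.ndarray, k_y: np.ndarray, alpha: float
) -> float:
    """- sum_i tr(S(X_i + delta, Y)) + alpha ||delta||_F.

    Rows are mean-centered before forming ``S`` (the correlation reading
    of the Gram matrices); the scale normalization is immaterial because
    ``S`` is invariant to per-channel scaling.
    """
    total = 0.0
    for x in xs:
        xc = _centered(x + delta)
        a_inv = _ridge_inv(xc @ xc.T)
        total += float(np.trace(a_inv @ xc @ k_y @ xc.T))
    return -total + alpha * float(np.linalg.norm(delta))


def trace_objective_grad(
    xs: np.ndarray, delta: np.ndarray, k_y: np.ndarray, alpha: float,
    fs: float = 250.0, band: tuple[float, float] = (7.0, 90.0),
) -> np.ndarray:
    """Exact gradient of :func:`trace_objective` w.r.t. the raw parameter r.

    d tr((XX^T)^-1 X K X^T)/dX = 2 A^-1 X K - 2 A^-1 X K X^T A^-1 X with
    A = XX^T (ridge included); centering contributes its own adjoint, and
    the band-limiting projection (self-adjoint) maps the result to
    r-space.
    """
    g = np.zeros_like(delta)
    for x in xs:
        xc = _centered(x + delta)
        a_inv = _ridge_inv(xc @ xc.T)
        xk = xc @ k_y
        gx = 2.0 * a_inv @ xk - 2.0 * a_inv @ xk @ xc.T @ a_inv @ xc
        g -= _centered(gx)  # centering is self-adjoint; objective is -sum
    nd = np.linalg.norm(delta)
    if alpha > 0 and nd > 0:
        g += alpha * delta / nd
    return filt(g, fs, band)


def optimize_template(
    train_block: list[SSVEPTrial],
    f_hat: float,
    config: SSVEPAttackConfig = SSVEPAttackConfig(),
    preproc: ssvep.SSVEPPreprocConfig = ssvep.SSVEPPreprocConfig(),
) -> SSVEPTemplate:
    """Craft the template for attacker frequency ``f_hat`` on one block.

    Gradient descent with normalized-gradient steps of fixed length
    (halved whenever the objective would increase), so the template
    energy grows gradually.  Terminates when the mean training-block SPR
    drops below ``spr_stop_db``; if ``max_iters`` is hit first the best
    iterate is returned with ``converged=False``.
    """
    if not train_block:
        raise ValueError("training block is empty")
    fs = train_block[0].fs
    xs = np.stack([ssvep.preprocess(t, preproc) for t in train_block])
    n_e, n_s = xs.shape[1:]
    k_y = _ref_projection(f_hat, fs, n_s, config.n_harmonics)
    # SPR is accounted against the raw trial samples the template is
    # added to, not the band-passed decoder view of them
    sig_energy = np.array([raw_window_energy(t, preproc.window_s) for t in train_block])

    def mean_spr(delta: np.ndarray) -> float:
        e = float(np.sum(delta**2))
        if e == 0:
            return float("inf")
        return float(np.mean(10.0 * np.log10(sig_energy / e)))

    rng = derive_rng(config.seed, TAG_ATTACK, int(round(f_hat * 10)))
    r = 1e-3 * rng.standard_normal((n_e, n_s))
    step = config.step_size
    delta = filt(r, fs, config.band)
    obj = trace_objective(xs, delta, k_y, config.alpha)
    log = [obj]
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        g = trace_objective_grad(xs, delta, k_y, config.alpha, fs, config.band)
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        # normalized-gradient step: the template energy grows by at most
        # ``step`` per iteration, so the SPR stop is crossed gently
        r_new = r - step * g / gn
        delta_new = filt(r_new, fs, config.band)
        obj_new = trace_objective(xs, delta_new, k_y, config.alpha)
        if obj_new > obj:
            step *= 0.5
            if step < 1e-12:
                break
            continue
        r, delta, obj = r_new, delta_new, obj_new
        log.append(obj)
        if mean_spr(delta) < config.spr_stop_db:
            converged = True
            break
    return SSVEPTemplate(
        delta=delta,
        attacker_freq=float(f_hat),
        raw=r,
        converged=converged,
        n_iters=it,
        train_spr_db=mean_spr(delta),
        objective_log=np.array(log),
    )


def inject(
    trial: SSVEPTrial, template: SSVEPTemplate, delay_samples: int = 0,
    window_s: tuple[float, float] = (0.13, 1.38),
) -> SSVEPTrial:
    """Add the template to the raw trial, aligned to the decoding window.

    The template is band-limited to the decoder's passband, so it reaches
    the CCA stage (nearly) unchanged by the zero-phase filtering.
    Samples outside the (shifted) window are untouched.
    """
    lo, hi = ssvep.window_bounds(window_s, trial.onset_sample, trial.fs)
    tlen = template.delta.shape[1]
    if hi - lo != tlen:
        raise ValueError("template length does not match the decoding window")
    lo += delay_samples
    n = trial.signal.shape[1]
    out = trial.signal.copy()
    b0, b1 = max(lo, 0), min(lo + tlen, n)
    if b1 > b0:
        out[:, b0:b1] += template.delta[:, b0 - lo : b1 - lo]
    return SSVEPTrial(out, trial.freq, trial.char, trial.onset_sample, trial.fs)


# ---------------------------------------------------------------------------
# noise baselines


def _scaled_to_spr(noise: np.ndarray, x: np.ndarray, spr_db: float) -> np.ndarray:
    e_n = float(np.sum(noise**2))
    if e_n == 0 or np.isinf(spr_db):
        return np.zeros_like(noise)
    e_s = float(np.sum(x**2))
    return noise * np.sqrt(e_s / (10.0 ** (spr_db / 10.0) * e_n))


def noise_baselines(
    session: SSVEPSession,
    kind: str,
    spr_db: float = 25.0,
    n_runs: int = 10,
    seed: int = 0,
    test_blocks: list[int] | None = None,
    freq_set: ssvep.FrequencySet | None = None,
    preproc: ssvep.SSVEPPreprocConfig | None = None,
) -> tuple[float, float]:
    """Decoding accuracy under random noise of matched energy.

    Kinds: ``gaussian`` white noise; ``single_periodic`` one sinusoid at
    a random stimulation frequency with phase uniform in [-pi/2, pi/2];
    ``compound_periodic`` a sum of such sinusoids over several
    stimulation frequencies with random amplitudes and phases.  The noise
    is added to the raw trial over the decoding window, scaled to
    ``spr_db`` against the raw window energy -- the same accounting as
    the adversarial template.  Returns (mean accuracy, mean SPR dB).
    """
    if kind not in ("gaussian", "single_periodic", "compound_periodic"):
        raise ValueError(f"unknown noise kind {kind!r}")
    freq_set = freq_set or ssvep.FrequencySet()
    preproc = preproc or ssvep.SSVEPPreprocConfig()
    if test_blocks is None:
        test_blocks = list(range(1, len(session.blocks)))
    trials = [t for b in test_blocks for t in session.blocks[b]]
    fs = session.fs
    n_s = ssvep.window_length(fs, preproc.window_s)
    t_axis = np.arange(n_s) / fs
    stim_freqs = np.asarray(freq_set.freqs)

    accs, sprs = [], []
    for run in range(n_runs):
        rng = derive_rng(seed, TAG_BASELINE, run)
        correct = 0
        run_sprs = []
        for t in trials:
            lo, hi = ssvep.window_bounds(preproc.window_s, t.onset_sample, fs)
            raw = t.signal[:, lo:hi]
            n_e = raw.shape[0]
            if np.isinf(spr_db):
                noise = np.zeros_like(raw)
            elif kind == "gaussian":
                noise = rng.standard_normal(raw.shape)
            elif kind == "single_periodic":
                f = rng.choice(stim_freqs)
                phase = rng.uniform(-np.pi / 2, np.pi / 2)
                wave = np.sin(2 * np.pi * f * t_axis + phase)
                noise = np.outer(rng.standard_normal(n_e), wave)
            else:  # compound_periodic
                n_comp = 5
                fsel = rng.choice(stim_freqs, size=n_comp, replace=False)
                noise = np.zeros_like(raw)
                for f in fsel:
                    phase = rng.uniform(-np.pi / 2, np.pi / 2)
                    amp = rng.uniform(0.2, 1.0)
                    wave = amp * np.sin(2 * np.pi * f * t_axis + phase)
                    noise += np.outer(rng.standard_normal(n_e), wave)
            noise = _scaled_to_spr(noise, raw, spr_db)
            run_sprs.append(spr(raw, noise) if noise.any() else float("inf"))
            perturbed = t.signal.copy()
            perturbed[:, lo:hi] += noise
            pt = SSVEPTrial(perturbed, t.freq, t.char, t.onset_sample, fs)
            f_dec, _ = ssvep.decode_trial(pt, freq_set, preproc)
            correct += abs(f_dec - t.freq) < 1e-9
        accs.append(correct / len(trials))
        sprs.append(np.mean(run_sprs))
    return float(np.mean(accs)), float(np.mean(sprs))
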