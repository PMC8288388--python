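"""Speller performance metrics and experiment assembly.

Scores
    ``user_score``: fraction of trials decoded as the character the user
    attended; ``attacker_score``: fraction decoded as the character the
    attacker targets.

Information transfer rate (bits/min)
    ``ITR = (1/T) [log2 Q + R log2 R + (1-R) log2((1-R)/(Q-1))]`` for a
    Q-character speller with accuracy R and selection time T minutes;
    set to 0 when R is at or below chance (R <= 1/Q).

Signal-to-perturbation ratio (dB)
    ``10 log10(||signal||_F^2 / ||perturbation||_F^2)``.  The "period"
    SPR restricts both to the perturbed samples; the "trial" SPR uses
    the whole trial, so it always exceeds the period SPR by the clean
    energy ratio of the two windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "itr",
    "user_attacker_scores",
    "spr",
    "EvalReport",
    "p300_selection_minutes",
    "delay_sweep_p300",
    "delay_sweep_ssvep",
    "run_p300_experiment",
    "run_ssvep_experiment",
]


def itr(r: float, q: int, t_minutes: float) -> float:
    """Information transfer rate in bits per minute."""
    if not (0.0 <= r <= 1.0):
        raise ValueError("accuracy R must lie in [0, 1]")
    if q < 2:
        raise ValueError("character count Q must be >= 2")
    if t_minutes <= 0:
        raise ValueError("selection time T must be positive")
    if r <= 1.0 / q:
        return 0.0
    bits = np.log2(q)
    if 0.0 < r < 1.0:
        bits += r * np.log2(r) + (1.0 - r) * np.log2((1.0 - r) / (q - 1))
    return float(bits / t_minutes)


def user_attacker_scores(
    true_chars: list[str], decoded_chars: list[str], attacker_char: str
) -> tuple[float, float]:
    if len(true_chars) != len(decoded_chars):
        raise ValueError("sequences must have equal length")
    if not true_chars:
        raise ValueError("empty input")
    n = len(true_chars)
    user = sum(d == t for d, t in zip(decoded_chars, true_chars)) / n
    attacker = sum(d == attacker_char for d in decoded_chars) / n
    return user, attacker


def spr(signal_segment: np.ndarray, perturbation_segment: np.ndarray) -> float:
    """Signal-to-perturbation ratio in dB; +inf for a zero perturbation."""
    if signal_segment.shape != perturbation_segment.shape:
        raise ValueError("segments must have equal shapes")
    e_p = float(np.sum(perturbation_segment**2))
    if e_p == 0.0:
        return float("inf")
    e_s = float(np.sum(signal_segment**2))
    return 10.0 * np.log10(e_s / e_p)


def p300_selection_minutes(n_repeats: int, soa_ms: float = 175.0) -> float:
    """Stimulation time per character: 12 intensifications per repeat."""
    return soa_ms * 12.0 * n_repeats / 1000.0 / 60.0


SSVEP_SELECTION_MINUTES = 1.25 / 60.0  # the decoded window per selection


@dataclass
class EvalReport:
    condition: str
    user_score: float
    user_itr: float
    attacker_score: float
    attacker_itr: float
    period_spr_db: float = float("nan")
    trial_spr_db: float = float("nan")
    seed: int = 0
    n_runs: int = 1

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "user_score": self.user_score,
            "user_itr": self.user_itr,
            "attacker_score": self.attacker_score,
            "attacker_itr": self.attacker_itr,
            "period_spr_db": self.period_spr_db,
            "trial_spr_db": self.trial_spr_db,
            "seed": self.seed,
            "n_runs": self.n_runs,
        }


# ---------------------------------------------------------------------------
# delay sweeps


def delay_sweep_p300(model, session, template, attacker_char, delays_ms, n_repeats=15):
    """User/attacker score as the injection is shifted in time."""
    from . import attack_p300

    truth = [t.target_char for t in session.trials]
    rows = []
    for d in delays_ms:
        decoded = attack_p300.attack_session(
            model, session, template, attacker_char, n_repeats, delay_ms=d
        )
        u, a = user_attacker_scores(truth, decoded, attacker_char)
        rows.append({"delay_ms": float(d), "user_score": u, "attacker_score": a})
    return rows


def delay_sweep_ssvep(session, template, test_blocks, delays_ms, freq_set=None, preproc=None):
    from . import attack_ssvep, ssvep

    freq_set = freq_set or ssvep.FrequencySet()
    preproc = preproc or ssvep.SSVEPPreprocConfig()
    trials = [t for b in test_blocks for t in session.blocks[b]]
    attacker_char = freq_set.char_for(template.attacker_freq)
    rows = []
    for d in delays_ms:
        delay = int(round(d / 1000.0 * session.fs))
        decoded, truth = [], []
        for t in trials:
            pt = attack_ssvep.inject(t, template, delay_samples=delay)
            decoded.append(ssvep.decode_trial(pt, freq_set, preproc)[1])
            truth.append(t.char)
        u, a = user_attacker_scores(truth, decoded, attacker_char)
        rows.append({"delay_ms": float(d), "user_score": u, "attacker_score": a})
    return rows


# ---------------------------------------------------------------------------
# experiment assembly (synthetic reproduction of the evaluation tables)


def run_p300_experiment(
    seed: int = 0,
    repeats: tuple[int, ...] = (5, 10, 15),
    attacker_chars: tuple[str, ...] | None = None,
    sim_config=None,
    n_noise_runs: int = 10,
) -> list[EvalReport]:
    """Clean / Gaussian-noise / adversarial rows per repeat count."""
    from . import attack_p300, p300, synth
    from .chars import P300_CHARS

    sim = sim_config or synth.P300SimConfig(seed=seed)
    train_sess = synth.make_p300_session(sim, "train")
    test_sess = synth.make_p300_session(sim, "test")
    model = p300.train(p300.P300ModelConfig(), train_sess)
    template = attack_p300.build_template(model, train_sess)
    truth = [t.target_char for t in test_sess.trials]
    chars_list = list(attacker_chars or P300_CHARS)

    reports: list[EvalReport] = []
    for nr in repeats:
        t_min = p300_selection_minutes(nr, sim.soa_ms)
        clean = p300.decode_session(model, test_sess, nr)
        u, _ = user_attacker_scores(truth, clean, "\0")
        reports.append(EvalReport(f"clean/r{nr}", u, itr(u, 36, t_min), 0.0, 0.0, seed=seed))

        # Gaussian-noise control, averaged over runs
        us, sprs = [], []
        for run in range(n_noise_runs):
            g = attack_p300.gaussian_template(model, seed=seed * n_noise_runs + run)
            # same injection schedule as an attack on a random character
            rng = np.random.default_rng(seed * n_noise_runs + run)
            ch = str(rng.choice(list(P300_CHARS)))
            decoded, pdb, _tdb = attack_p300.attack_session(
                model, test_sess, g, ch, nr, with_spr=True
            )
            us.append(user_attacker_scores(truth, decoded, ch)[0])
            sprs.append(np.mean(pdb))
        um = float(np.mean(us))
        reports.append(
            EvalReport(
                f"gaussian/r{nr}", um, itr(um, 36, t_min), 0.0, 0.0,
                period_spr_db=float(np.mean(sprs)), seed=seed, n_runs=n_noise_runs,
            )
        )

        us, as_, pdbs, tdbs = [], [], [], []
        for ch in chars_list:
            decoded, pdb, tdb = attack_p300.attack_session(
                model, test_sess, template, ch, nr, with_spr=True
            )
            u, a = user_attacker_scores(truth, decoded, ch)
            us.append(u)
            as_.append(a)
            pdbs.append(np.mean(pdb))
            tdbs.append(np.mean(tdb))
        reports.append(
            EvalReport(
                f"attack/r{nr}",
                float(np.mean(us)),
                itr(float(np.mean(us)), 36, t_min),
                float(np.mean(as_)),
                itr(float(np.mean(as_)), 36, t_min),
                period_spr_db=float(np.mean(pdbs)),
                trial_spr_db=float(np.mean(tdbs)),
                seed=seed,
                n_runs=len(chars_list),
            )
        )
    return reports


def run_ssvep_experiment(
    seed: int = 0,
    attacker_freqs: tuple[float, ...] | None = None,
    sim_config=None,
    train_block: int = 0,
    n_noise_runs: int = 10,
) -> list[EvalReport]:
    """Clean / noise baselines / adversarial rows for one synthetic subject."""
    from . import attack_ssvep, ssvep, synth

    sim = sim_config or synth.SSVEPSimConfig(seed=seed)
    session = synth.make_ssvep_session(sim)
    freq_set = ssvep.FrequencySet(freqs=tuple(np.round(sim.freqs, 10)))
    preproc = ssvep.SSVEPPreprocConfig()
    test_blocks = [b for b in range(len(session.blocks)) if b != train_block]
    trials = [t for b in test_blocks for t in session.blocks[b]]
    truth = [t.char for t in trials]
    t_min = SSVEP_SELECTION_MINUTES
    q = len(freq_set.freqs)

    reports: list[EvalReport] = []
    clean = [ssvep.decode_trial(t, freq_set, preproc)[1] for t in trials]
    u, _ = user_attacker_scores(truth, clean, "\0")
    reports.append(EvalReport("clean", u, itr(u, q, t_min), 0.0, 0.0, seed=seed))

    for kind in ("gaussian", "single_periodic", "compound_periodic"):
        u, sprdb = attack_ssvep.noise_baselines(
            session, kind, test_blocks=test_blocks, freq_set=freq_set, preproc=preproc,
            n_runs=n_noise_runs, seed=seed,
        )
        reports.append(
            EvalReport(
                f"noise/{kind}", u, itr(u, q, t_min), 0.0, 0.0,
                trial_spr_db=sprdb, seed=seed, n_runs=n_noise_runs,
            )
        )

    freqs = attacker_freqs or freq_set.freqs
    cfg = attack_ssvep.SSVEPAttackConfig(seed=seed)
    us, as_, sprs = [], [], []
    for f_hat in freqs:
        tmpl = attack_ssvep.optimize_template(session.blocks[train_block], f_hat, cfg, preproc)
        decoded, sdb = [], []
        for t in trials:
            pt = attack_ssvep.inject(t, tmpl)
            decoded.append(ssvep.decode_trial(pt, freq_set, preproc)[1])
            sdb.append(attack_ssvep.template_spr_db(t, tmpl, preproc.window_s))
        u, a = user_attacker_scores(truth, decoded, freq_set.char_for(f_hat))
        us.append(u)
        as_.append(a)
        sprs.append(np.mean(sdb))
    reports.append(
        EvalReport(
            "attack", float(np.mean(us)), itr(float(np.mean(us)), q, t_min),
            float(np.mean(as_)), itr(float(np.mean(as_)), q, t_min),
            trial_spr_db=float(np.mean(sprs)), seed=seed, n_runs=len(list(freqs)),
        )
    )
    return reports
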