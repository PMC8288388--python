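# spellbreak

Adversarial perturbation templates for EEG-based brain–computer-interface
(BCI) spellers — a reproducible security testbed for the two classic
paradigms, P300 and SSVEP, built entirely on synthetic EEG.

BCI spellers let a user type by attention alone: a P300 speller flashes
the rows and columns of a 6×6 character matrix and detects the P300
evoked potential elicited by the attended row/column; an SSVEP speller
flickers 40 characters at distinct frequencies (8–15.8 Hz in 0.2 Hz
steps) and identifies the attended one from the steady-state oscillation
at that frequency and its harmonics. `spellbreak` implements both victim
decoders, and the attack that matters for their security analysis: a
**fixed perturbation template**, orders of magnitude smaller than the
ongoing EEG, that is computed once from training data and then injected
at stimulus-locked times to force the decoder to output any character
the attacker chooses. Because the template never depends on the trial
being attacked, the attack is *causal* and could run online.

It is intended for researchers studying adversarial robustness of
neural decoders: every stage — synthetic data, victim training, template
construction, injection, evaluation — is a tested library function with
a CLI on top, and runs in minutes on one CPU.

## What is implemented

- **Synthetic sessions** (`spellbreak.synth`): P300 oddball recordings
  (continuous 16-channel signal, 12 random intensifications per repeat
  at a 175 ms stimulus onset asynchrony, raised-cosine target
  deflection, 1/f background, per-channel z-normalization) and SSVEP
  sessions (6 blocks × 40 trials, 9 posterior channels, harmonics with
  a 140 ms onset delay over a 1/f² + broadband-floor background).
- **P300 victim model** (`spellbreak.p300`, `spellbreak.riemann`):
  0–600 ms epochs → 16 xDAWN filters → 32×32 super-trial covariances →
  tangent space at the affine-invariant geometric mean → class-weighted
  logistic regression → probability-sum voting over repeats. The model
  is differentiable end to end; exact input gradients are provided.
- **SSVEP victim model** (`spellbreak.ssvep`): 7–90 Hz zero-phase
  band-pass, [0.13, 1.38) s window, canonical correlation against
  5-harmonic sine/cosine reference banks, argmax over 40 frequencies,
    ρ(X, Y_f) = sqrt(λ_max((XXᵀ)⁻¹ X Y_fᵀ (Y_f Y_fᵀ)⁻¹ Y_f Xᵀ)).
- **P300 attack** (`spellbreak.attack_p300`): sum of normalized
  input-gradient directions over training nontarget epochs, band-passed
  0.1–15 Hz, truncated to 350 ms, per-channel L2 norm ε = 0.5; injected
  at the attacker character's row/column flash onsets.
- **SSVEP attack** (`spellbreak.attack_ssvep`): a band-limited template
  δ = filt(r) optimized by gradient descent on
    −Σ_X tr(S(X + filt(r), Y_f̂)) + α‖filt(r)‖_F,
  stopping when the training-block signal-to-perturbation ratio falls
  below 25 dB.
- **Controls and metrics** (`spellbreak.evaluate`): energy-matched
  Gaussian and periodic noise baselines, user/attacker scores,
  information transfer rate (Wolpaw), period/trial SPRs, and
  synchronization-delay sweeps.

## Worked example

```python
import numpy as np
from spellbreak import synth, p300, attack_p300, evaluate

cfg = synth.P300SimConfig(n_train_chars=10, n_test_chars=8, seed=7)
train = synth.make_p300_session(cfg, "train")
test = synth.make_p300_session(cfg, "test")

model = p300.train(p300.P300ModelConfig(), train)
template = attack_p300.build_template(model, train)   # fixed before test time

truth = [t.target_char for t in test.trials]
clean = p300.decode_session(model, test, n_repeats=15)
attacked, period_db, trial_db = attack_p300.attack_session(
    model, test, template, attacker_char="Z", n_repeats=15, with_spr=True
)

user, _ = evaluate.user_attacker_scores(truth, clean, "Z")
user_atk, attacker = evaluate.user_attacker_scores(truth, attacked, "Z")
t_min = evaluate.p300_selection_minutes(15)
print(f"truth     : {''.join(truth)}")
print(f"clean     : {''.join(clean)}   user score {user:.2f}")
print(f"attacked  : {''.join(attacked)}   user score {user_atk:.2f}, "
      f"attacker score {attacker:.2f}")
print(f"attacker ITR {evaluate.itr(attacker, 36, t_min):.2f} bits/min")
print(f"period SPR {np.mean(period_db):.1f} dB, trial SPR {np.mean(trial_db):.1f} dB")
```

Output:

```
truth     : OW3RRBJY
clean     : OW3RRBJY   user score 1.00
attacked  : ZZZZZZZZ   user score 0.00, attacker score 1.00
attacker ITR 9.85 bits/min
period SPR 25.1 dB, trial SPR 30.1 dB
```

The clean decoder spells every attended character; after injection the
speller outputs the attacker's `Z` on every trial, while the
perturbation sits 25 dB below the signal in the perturbed periods
(30 dB over whole trials) — too small to spot in the trace.

The same flow drives the CLI:

```bash
spellbreak simulate p300 --seed 1 --split train --out train.h5
spellbreak simulate p300 --seed 1 --split test  --out test.h5
spellbreak train  --session train.h5 --out model.h5
spellbreak attack p300 --model model.h5 --session train.h5 --out template.h5
spellbreak evaluate --model model.h5 --session test.h5 \
    --template template.h5 --attacker-char Z --repeats 15
spellbreak sweep-delay --model model.h5 --session test.h5 \
    --template template.h5 --attacker-char Z --delays-ms 0,87.5,175
```

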