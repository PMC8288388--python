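# Methods

`spellbreak` studies a security property of EEG-based brain–computer-
interface spellers: a fixed, pre-computed "adversarial perturbation
template" — a short multichannel waveform far too small to notice in the
EEG trace — can be added to the signal at stimulus-locked times and
steer the speller's output to any character an attacker chooses. Because
the template is built once from training data and never depends on the
trial being attacked, the attack is *causal*: it can run online, unlike
perturbations that require the whole trial before they are computed.

Everything runs on synthetic EEG so the full loop (simulate → train
victim → craft template → inject → evaluate) is reproducible on one CPU
with no external data.

## Victim models

**P300 speller.** A 6×6 character matrix; rows and columns flash in
random order (100 ms flash + 75 ms blank, so one stimulus onset
asynchrony is 175 ms), 12 flashes per repeat, 15 repeats per character.
The decoder is the classical Riemannian pipeline: 0–600 ms epochs per
flash; 16 xDAWN spatial filters (8 per class) obtained from the
generalized eigenproblem of synchronized-average evoked power against
total signal power; each filtered epoch is stacked with the filtered
class-mean evoked templates into a 32-row "super-trial" whose
row-centered covariance (with trace-preserving shrinkage, γ = 0.01) is
mapped to the tangent space at the affine-invariant geometric mean of
the training covariances; a class-weighted logistic regression (weights
inversely proportional to class counts, i.e. 5:1 for the 10-vs-2
design) scores the tangent vectors. Character decoding sums predicted
target probabilities per stimulus id over repeats and takes the argmax
row and column (ties to the lowest id). Probability-sum voting is the
differentiable reading of "voting"; the super-trial composition
(target + nontarget templates + 16-filter projection, 32×32) follows
the Kaggle-lineage construction and is configurable.

The whole map from epoch samples to probability is smooth (shrinkage
keeps every covariance positive-definite), and `loss_gradient` returns
the exact input gradient by chaining the logistic derivative, the
√2-weighted vectorization, the Daleckii–Krein adjoint of the matrix
logarithm, the shrinkage and centering adjoints, and the fixed spatial
projection. Tests verify it against central finite differences at
relative error < 1e−4.

**SSVEP speller.** 40 characters flicker at 8–15.8 Hz in 0.2 Hz steps
(5×8 matrix, frequencies assigned column-major). A trial is band-passed
7–90 Hz (zero-phase 4th-order Butterworth), windowed to [0.13, 1.38) s
after stimulus onset (the cortical response lags the stimulus by
130–140 ms), and compared by canonical correlation against a
sine/cosine reference bank of 5 harmonics per candidate frequency; the
argmax frequency wins. The window rule is floor at both ends, half-open,
giving 313 samples at 250 Hz. CCA is computed as the largest singular
value of the whitened cross-product with ridge-stabilized Gram inverses
(ε = 1e−8·tr/m); rows are z-normalized per channel/reference row, the
convention that makes the Gram expression a correlation operator.

## Attacks

**P300 template.** For every nontarget training epoch the input-gradient
direction that raises the target probability is normalized by its
Frobenius norm; the directions are summed, band-passed to 0.1–15 Hz
(zero-phase, reflect padding), truncated to the first 350 ms (two
stimulus periods, 84 samples at 240 Hz), normalized to unit L2 per
channel, and scaled by ε = 0.5. One sign convention is worth stating:
the summed *loss-gradient toward the flipped label* points away from the
target class, so the template is the loss-descent (logit-ascent)
direction — the orientation that actually raises the target probability,
which the tests assert directly. At attack time the template is added at
the onsets of the attacker character's row and column flashes;
overlapping additions sum without rescaling; samples outside the
injection windows are untouched.

**SSVEP template.** CCA has no fixed parameters to attack (its weights
are re-fit per trial), so the template is optimized directly on the
first block D: minimize
`−Σ_{X∈D} tr(S(X + filt(r), Y_f̂)) + α‖filt(r)‖_F` over the raw
parameter r, where `filt` zeroes all DFT bins outside 7–90 Hz — an
exact, idempotent, self-adjoint projection, so the template passes the
decoder's band-pass essentially unchanged. The trace of the CCA matrix
S stands in for its largest eigenvalue; α = 0.05 (the energy penalty
mostly shapes the path — the SPR stop pins the final magnitude).
Optimization is plain gradient descent with normalized-gradient steps
(0.05 per step, halved if the objective rises), so the template energy
grows gently; it stops the first time the mean signal-to-perturbation
ratio over the training block drops below 25 dB, which lands the final
SPR just under the threshold rather than overshooting it. The rows of
X are mean-centered inside the objective (scale normalization is
immaterial: S is invariant to per-channel scaling). r is initialized to
small seeded white noise.

**Controls.** The Gaussian control for the P300 attack applies the
identical post-processing to standard Gaussian noise, so it matches the
adversarial template's per-channel energy exactly. The SSVEP noise
baselines (white noise; one sinusoid at a random stimulation frequency,
phase uniform in [−π/2, π/2]; a compound of five such sinusoids with
random amplitudes) are injected into the raw trial over the decoding
window and scaled per trial to 25 dB SPR, the same energy accounting as
the template.

## Metrics

*User score* is the fraction of trials decoded as the attended
character; *attacker score* the fraction decoded as the attacker's
character. The information transfer rate for a Q-character speller at
accuracy R and selection time T minutes is
`ITR = (1/T)[log₂Q + R log₂R + (1−R) log₂((1−R)/(Q−1))]`, set to 0 at or
below chance (R ≤ 1/Q). P300 selection time defaults to stimulation
time only (0.175 s × 12 × repeats); SSVEP to the 1.25 s decoded window —
both configurable, since published ITRs embed unstated per-selection
overheads and are therefore validated here through the analytic
identities rather than against table values. The signal-to-perturbation
ratio is `10·log₁₀(‖signal‖²_F/‖perturbation‖²_F)`; the *period* SPR
restricts both to the perturbed samples, the *trial* SPR uses the whole
trial, and for the SSVEP attack the SPR is accounted against the raw
(unfiltered) trial samples the template is added to.

## Synthetic data: what it emulates, and what it does not

**P300 sessions** are continuous 16-channel recordings at 240 Hz with
85 train / 100 test character trials, a full random 12-flash schedule
per repeat, and a raised-cosine target deflection (center 300 ms after
flash onset, width 200 ms, amplitude 0.7 before normalization) projected
through a fixed smooth scalp pattern, on top of spatially mixed 1/f
background noise; each channel is z-normalized over the recording. The
raised cosine is a deliberate minimal model of the P300 — band-limited
and confined to the 250–500 ms window; its amplitude satisfies the
calibration regime the pipeline is designed for (training balanced
accuracy ≥ 0.85, clean epoch AUC > 0.9).

**SSVEP sessions** are 6 blocks × 40 trials of 9-channel, 250 Hz, 6 s
trials (0.5 s pre-stimulus); from 140 ms after onset the trial carries
3 harmonics of its flicker frequency with 1/h amplitude decay and
random phases, projected through a posterior channel profile, scaled to
−26 dB SNR against the background over the stimulation span, then
z-normalized per channel. The background is 1/f² noise (the spectral
slope of raw EEG, which concentrates most trial energy below the
decoder's 7 Hz passband edge) plus a 20% flat broadband floor standing
in for sensor/EMG noise, spatially mixed by a fixed per-subject
full-rank matrix. Both the slope and the floor are load-bearing: with a
flat-ish background, CCA is unrealistically easy, the evoked component
must be made so strong that a 25 dB-SPR template cannot compete, and
the attack's published operating point is unreachable; with no
broadband floor, the harmonic bands above ~16 Hz are unrealistically
silent and even energy-matched white noise disturbs the decoder. The
chosen background reproduces the published regime: clean accuracy
≈ 0.85–0.90, Gaussian noise harmless, single-frequency periodic noise
the most damaging non-adversarial perturbation, and template attacks
succeeding at the 25 dB stop.

The subject-level constants (spatial mixing, channel patterns) are
derived from the seed independently of the split, so train and test
recordings of one subject share covariance structure, as real split
recordings do.

Not modeled: eye-blink/EMG artifact events, ERP latency/amplitude
variability, inter-subject variability beyond the seed, alpha-band
rhythms with 1/f-deviating peaks, and non-stationarity. Consequences:
the synthetic P300 subject is cleaner than the published subjects —
clean user scores saturate near 1.0 at 5–15 repeats where real subjects
span 0.64–0.93 — so passing tests demonstrate the pipeline and attack
mechanics at the published operating points (ε = 0.5, 25 dB SPR), not
that the attack would achieve identical scores on recorded EEG.

## Numerical choices

- Geometric mean: fixed-point iteration from the arithmetic mean,
  tolerance 1e−8 on the mean tangent update, max 50 iterations
  (non-convergence raises).
- Shrinkage γ = 0.01 guarantees positive-definiteness and hence
  differentiability for all finite inputs.
- CCA ridge ε = 1e−8·tr/m on both Gram matrices; ρ clipped to [0, 1].
- Sample indexing is 0-based; epoch and decoding windows are half-open
  [onset, onset + len).
- Ties in argmax decoding break toward the lowest stimulus id / lowest
  frequency.
- Logistic regression: lbfgs to tolerance 1e−10, C = 1.0 (weak penalty,
  ~1/n relative to the per-sample loss).
- All randomness derives from one master seed through tagged
  `SeedSequence` spawn keys (generator splits, attack initialization,
  baseline runs, subject constants).
- Template filtering of short windows uses zero-phase `sosfiltfilt`
  with its reflect padding; the SSVEP band-limiter is a DFT mask, which
  zeroes bin-exact out-of-band tones exactly and attenuates off-grid
  ones by finite-window leakage only.

## Problem sizes

Acceptance-level runs use the full stated conditions: P300 with 85
training and 100 test characters at 15 repeats (18 000 test epochs) and
all 36 attacker characters; SSVEP with 6 blocks × 40 trials and all 40
attacker templates evaluated on the 200 held-out trials. Unit and
property tests use smaller subjects (8–10 characters, 2 blocks) with
identical schedule structure.

## Known limitations

- The trace surrogate is taken as given; no bound relating tr(S) to
  λ_max(S) is re-derived.
- The P300 attack assumes exact stimulus-onset knowledge; the delay
  sweep quantifies (and the tests assert) its synchronization
  sensitivity, in contrast to the SSVEP template's delay robustness.
- Real-data loaders for the public benchmark formats are out of scope;
  the HDF5 container documents an extension point.
- Cross-subject/cross-model transferability of templates is not
  implemented.
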