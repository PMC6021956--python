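# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `hbcikit`.

## Experimental paradigm being modelled

A session consists of 30 cued trials, 10 each of mental arithmetic (MA),
word chain (WC) and relaxed baseline (BL), in seeded random order. Each
trial is a 2-s visual instruction, a 5-s task period, and a rest period
drawn uniformly from 13–15 s; a subject contributes 3 sessions (90 trials).
Pre/post-session rest defaults to 60 s (configurable; shorter values are
equally valid for simulation purposes). Only the two binary problems
MA-vs-BL and WC-vs-BL are evaluated; MA-vs-WC and the ternary problem are
out of scope because the frontal patterns of the two active tasks overlap
too strongly for single-trial separation.

## Synthetic-data generator (`simgen`)

The generator is first-class, tested code. It emulates the *statistical
structure* the analysis relies on, not the biophysics of any head model.

**EEG** (10 frontal channels, 200 Hz, µV). Each filter-bank band (θ, α, β)
has one band-limited Gaussian source mixed into the channels through a
fixed, dataset-level spatial pattern, on top of per-channel pink (1/f)
noise. During task windows the source envelope is multiplied by
`1 − erd_depth[class][band]` (event-related desynchronization) or
`1 + ers_gain` (synchronization), with 0.5-s raised-cosine ramps at the
window edges. Defaults: MA shows α ERD 0.5, β ERD 0.3 and θ ERS 0.4; WC
shows α ERD 0.45 and β ERD 0.40; BL has no effects. Oscillation pattern
scales are 1.5/2.0/1.25 µV (θ/α/β) against a 16-µV pink background.

**EOG.** Poisson blink/saccade events (0.1 Hz, ~100 µV Gaussian pulses) on
two bipolar channels, leaking into EEG channels with fixed coefficients
(0.15 frontopolar, decaying posteriorly).

**NIRS** (9 prefrontal channels, 12.5 Hz, mol/L). Per task trial, HbO rises
as the canonical double-gamma impulse response (peak 6 s, undershoot 16 s,
ratio 1/6) convolved with the 5-s task boxcar, normalized to a peak
amplitude of ~1 µM (WC left-lateralised); HbR is a 0.5-s-delayed copy
scaled by −0.3. Structured noise: Mayer wave (0.1 Hz, 0.8 µM), respiration
(0.3 Hz), cardiac (1.1 Hz), a <0.01-Hz drift, and white noise (3 µM before
band-pass filtering, ~0.5 µM within the analysis band). Systemic noise is
added to HbO and, half-scaled and sign-flipped, to HbR. Optionally the
generator emits dual-wavelength optical density through the forward
Beer–Lambert model so the inversion is exercised end to end.

**Trial-to-trial and session-to-session variability.** Two mechanisms make
the data realistically imperfect rather than deterministic:

* *trial jitter* (default 0.5): each trial's deviation from unit gain (EEG)
  or HRF amplitude (NIRS) is scaled by `clip(N(1, 0.5²), 0, 2)`, modelling
  fluctuating task engagement;
* *session drift* (default 0.35): per-session multiplicative jitter of the
  band spatial patterns and HRF amplitude maps, modelling cap/optode
  re-mounting and day-to-day state differences. Drift is what makes the
  chronological (pseudo-online) split systematically harder than mixed
  cross-validation, as observed with real multi-session recordings.

Effect sizes and noise levels were chosen once so the three decoders land
in the 75–85 % unimodal / ≳85 % hybrid accuracy range typical of frontal
mental-task BCIs; they are configuration, not constants.

**Determinism.** All draws flow from `SimConfig.seed`; per-session streams
are keyed `(seed, session, purpose)`, so identical configs give
bit-identical datasets and sessions are reproducible yet independent.

**What the generator does not model** — and hence what passing tests do not
show about real data: no volume-conducted source mixing beyond the fixed
patterns, no non-stationary artifacts (motion, electrode pops), no
superficial/systemic NIRS contamination with task-locked components, no
initial-dip dynamics, no subject non-responders. Pipeline performance on
this generator demonstrates correctness of the machinery, not expected
field performance.

## Preprocessing (`preprocess`)

* EEG: 1–40 Hz Butterworth, overall order 4, applied forward–backward
  (the family/order of this filter is a package choice; zero-phase keeps
  epoch timing intact). EOG correction defaults to least-squares regression
  on the EOG channels — deterministic and sufficient for linear leakage;
  fixed-seed FastICA with |r| > 0.7 component rejection is available, as is
  `none` (the analysis must also run uncorrected). Decimation to 100 Hz uses
  a 129-tap FIR (cutoff 0.8 × new Nyquist) applied zero-phase, then takes
  every k-th sample and re-indexes markers.
* Pipeline order is filter → EOG-correct → decimate (configurable); the
  order is not dictated by the method.
* NIRS: modified Beer–Lambert inversion with wavelengths 760/850 nm,
  extinction coefficients (586, 1548.52; 1058, 691.32) 1/(mol/L·cm), DPF 6.0
  at both wavelengths, 3.0 cm separation — standard tabulated constants, all
  configurable. Then 0.01–0.2 Hz Butterworth of overall order 6,
  forward–backward (≥ 40 dB at 0.5 Hz after two passes).
* Epochs span the closed interval [−5, 5] s with time 0 exactly on the
  marker sample: 1001 samples at 100 Hz. At 12.5 Hz the ±5 s edges are not
  on the sample grid; the 126-sample grid starts at `ceil(−5·fs)` so that
  offset 0 is always included (window [−4.96, 5.04] s). Baseline correction
  subtracts the per-trial, per-channel mean over [−5, −2] s (the instruction
  starts at −2 s, so later baseline samples could already contain task
  activity); it is applied to both EEG and chromophore epochs.

## Features (`features`)

* CSP per band on the class pair: trial covariances over the 0–5 s window
  are trace-normalized before within-class averaging (robustness to
  per-trial broadband power; `trace_norm=False` restores exact invariance
  under invertible channel mixing), the pooled matrix is regularized by
  `1e-9 · trace/d · I` only if rank-deficient, eigenvalues are clipped to
  [0, 1] and sorted descending, and each filter's sign is fixed by making
  its largest-magnitude entry positive. Features are log raw variances of
  the first/last three components (18 total); CSP is refitted inside every
  training fold.
* NIRS: per channel and sub-window (half-open [t₀, t₁), last window closed
  so the three windows partition [0, 5] s exactly), the mean and the
  least-squares slope (mol/L/s). "Average slope" could also be read as
  endpoint difference over duration; least squares is the default and
  `slope_method="endpoint"` switches.

## Classification (`classify`)

* Shrinkage LDA toward the scaled identity `νI`, `ν = trace/D`. The printed
  form of the shrunk matrix in the source method is `(1−λ)Σ + λI`, but an
  unscaled identity target is not invariant to feature units and the cited
  shrinkage lemma targets a scaled identity; a strict `target="identity"`
  mode is provided for comparison.
* The analytic intensity uses the Schäfer–Strimmer unbiased-variance
  scaling — the standard "Ledoit–Wolf" formula of shrinkage LDA in the
  neurophysiology literature — which equals the original Ledoit–Wolf
  intensity times `n/(n−1)` before clipping to [0, 1]. Note the lemma's
  behaviour: when the true covariance is itself spherical the target
  coincides with the truth and λ is large regardless of n; λ → 0 with
  growing n only for a non-spherical truth.
* Pooled within-class covariance divides by n − 2 (two classes); this
  affects only the scale of `w`, never a decision.
* Decision `f(x) = w·x − b`, positive ⇒ first class of the pair; an exact 0
  goes to the second class (deterministic tie-break).
* Meta-classifier: base sLDAs per modality; their continuous decision
  values on *out-of-fold* trials (inner stratified 5-fold CV on the training
  set, stratified by class × session when cell sizes allow) train the
  second-layer sLDA; base models are then refitted on all training trials
  for deployment. Training the meta layer on resubstitution outputs
  (`mode="naive"`) is available but overfits the base decision scale.

## Evaluation (`evaluate`)

* Offline: 10 × 5-fold stratified CV over the pooled trials of the pair.
  Folds are stratified by class × session (falling back to class alone for
  tiny cells) so per-session drift cannot anti-correlate between training
  and test folds — with class-only stratification the null distribution of
  CV accuracy acquires a below-chance bias from exactly that confound.
  Fold membership is keyed on trial *content* (hash), making every reported
  accuracy exactly invariant to the order trials are supplied in.
* Null calibration: cross-validated accuracy on no-signal data is still
  slightly pessimistic (training class means anti-correlate with held-out
  fold composition); per-subject accuracies stay inside the exact binomial
  95 % interval at n = 60, and the bias direction cannot mask leakage.
* Pseudo-online: `causal` trains on all sessions but the last and tests on
  the last (train 40 trials = 20 per class, test 20, with default counts);
  `session_cv` leaves each session out in turn. The bracketed per-session
  counts in the source description are per class.
* Learning curve: for each n, stratified subsets of the earlier sessions'
  trials (n/2 per class) train the pipeline, tested on the last session;
  with the full pool and one resample it reproduces the causal result
  exactly.
* ITR: `m = 60 / trial_len_s` with `trial_len_s = 5` by default — the
  decision time excludes instruction and rest, matching how the theoretical
  ITR for a 5-s trial is quoted. ITR is convex in P on (0.5, 1] for N = 2,
  so the ITR at a group-mean accuracy lower-bounds the group-mean of
  per-subject ITRs (Jensen); the acceptance script reports the bound values.
* Statistics: Friedman omnibus across the three modalities; pairwise
  Wilcoxon signed-rank (exact for n ≤ 25 without zero differences, normal
  approximation with continuity correction otherwise); Benjamini–Hochberg
  step-up as the FDR procedure. Identical columns short-circuit to
  statistic 0 / p 1 with a warning.
* Chance level: smallest k/n with exact binomial tail P(X ≥ k | p = 0.5)
  < α; saturates at 1.0 when no achievable count is significant, and α ≥ 1
  returns 0 by convention.
* ERD/S maps: Hann-tapered sliding-window spectra, zero-padded by the pad
  ratio, averaged over trials and channels, in dB relative to the
  per-frequency baseline mean; class-difference maps subtract dB values.
  With 10-s epochs, a 5.12-s window leaves no window centers inside
  [−5, −2] s, so shorter windows are used when a pre-task baseline is
  required.

## Problem sizes used in tests and the acceptance script

Ten synthetic subjects (one per seed), 3 sessions × 30 trials each, offline
10 × 5-fold CV, pseudo-online causal split, plus a ten-subject null cohort
(5 × 5-fold); the full acceptance run completes in about two minutes on one
CPU. These sizes match the emulated study design; larger cohorts only
tighten the cohort means.

## Known limitations

* The generator's effects are stationary within a session apart from trial
  jitter; slow within-session fatigue trends are not modelled.
* The meta-classifier fuses exactly the three fixed modalities; no
  per-subject modality selection.
* ICA-based EOG correction uses plain FastICA on the (few) EEG channels and
  a correlation threshold; it is a faithful but minimal stand-in for
  toolbox-grade artifact pipelines.
* No reader adapters for vendor file formats are bundled; the container
  format plus the documented in-memory types are the interface.
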