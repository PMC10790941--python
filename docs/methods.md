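# Methods

`nitrack` implements a subject-independent EEG marker of task proficiency
for single-session training protocols, together with a synthetic cohort
generator that reproduces the statistical structure the analysis assumes.
This note documents the model, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## The analysis model

**Design.** A participant completes 60 navigation trials in 10 blocks of
6 (up to 3 min per trial). A 1-min eyes-open rest precedes every block;
1-min eyes-closed rests open and close the session. After each trial the
participant rates how certain they were of the route (1–10); the trial's
completion time is expressed as percent excess over an "ideal" time,
`100 · (t − t_ideal)/t_ideal`.

**Band power.** EEG (64-channel 10–20 montage, 500 Hz, FCz reference) is
downsampled to 256 Hz, band-passed 1–50 Hz with a zero-phase FIR, and an
optional artifact-removal hook is applied (identity by default — the
synthetic data are artifact-free by construction; the hook accepts any
recording→recording transform). The individual alpha frequency (IAF) is
the mean over the two eyes-closed rests of the argmax of the
occipital-averaged Welch spectrum (4 s windows, 50% overlap, 0.25 Hz grid)
in 8–15 Hz; a flat spectrum (max < 2× the in-band median) raises a no-peak
error, with an optional 10 Hz fallback. Four contiguous 2 Hz bands are
anchored at the IAF: theta `[IAF−6, IAF−4]`, alpha-low1 `[IAF−4, IAF−2]`,
alpha-low2 `[IAF−2, IAF]`, alpha-high `[IAF, IAF+2]`. Per band, a
filter–Hilbert power series (zero-phase FIR to the band, squared analytic
envelope) is z-scored per channel against the session's *first eyes-open
rest*, so all downstream features are in baseline-relative units.

**Features and labels.** Each navigation trial is cut into non-overlapping
1 s epochs (trailing partial second discarded); an epoch's features are the
mean z-scored power per channel and band over a 41-channel subset covering
frontal, temporal, parietal and occipital regions (central-strip rows FC*,
C*, CP* excluded), i.e. 41 × 4 = 164 features. Trials are ranked by
ascending certainty with completion order breaking ties; the bottom 10% of
trials become class 0 ("low proficiency") and the top 10% class 1
(6 + 6 trials at n = 60; `max(2, floor(0.1·n))` in general).

**Classification.** For each held-out participant, and in each of 100 runs:
every *training* participant's labeled epochs are balanced by subsampling
the larger class without replacement; greedy mRMR (MID criterion,
mutual information on equal-frequency 3-bin discretized features, ties to
the lowest feature index within a 1e-12 relative tolerance) picks 10
features from the pooled balanced epochs; a linear SVM (C = 1, features
standardized by training statistics) is fit and predicts the class of
*every* navigation epoch of the held-out participant. The test set is fixed
across runs; no held-out epoch ever enters selection or training.

**Neural indicator.** NI of trial *t* is the mean predicted class over the
trial's epochs, with per-epoch predictions first averaged over runs:
`NI_t = (1/n_t) Σ_i c̄_i`. Because the test set is fixed, this equals the
mean over runs of per-run trial NIs (asserted in tests). Block NI is the
unweighted mean of its trials' NIs (an epoch-weighted variant would
down-weight short late trials; the unweighted form matches a
per-block-mean-of-trials reading and is the default).

**Statistics.** The session trend is a repeated-measures linear mixed model
`NI ~ 1 + block` with a random intercept per participant (REML). The
p-value uses the normal approximation to the slope's t statistic; the
conventional df `n_obs − n_participants − 1` is reported alongside. A
singular fit falls back to OLS with cluster-robust (by participant)
standard errors, flagged in the result. Per participant, Pearson r relates
trial NI to certainty and to time performance, over all trials and over the
first and last 20% of trials. Significance of a participant's
*block-extremes accuracy* (first-block epochs scored correct when predicted
0, final-block epochs when predicted 1) comes from a permutation null:
training labels are shuffled within each training participant (class counts
preserved) and the identical balance→mRMR→SVM procedure is re-run; with
1000 permutations this costs 1000× the true analysis, so each permutation
uses a single run by default (`runs_per_perm` overrides) — this leaves the
null's location unbiased and only widens it slightly. p is the proportion
of null accuracies ≥ the true one, and a participant is flagged "effective"
when p clears `max(α, 1/n_perm)` with α = 0.001.

## The synthetic cohort generator

Each participant's session is synthesized segment by segment in µV:

- **Background:** 1/f^β noise per channel (β ~ U[0.85, 1.15] per
  participant), with an *absolute* spectral scale calibrated so the
  1 Hz–Nyquist band has variance `noise_scale²` (10 µV r.m.s.) regardless
  of segment length. Per-segment empirical normalization is deliberately
  avoided: it couples band-limited noise power to segment duration, which
  injects a spurious trial-length class signal (long early trials vs short
  late trials) that a classifier happily exploits.
- **Theta:** a constant-amplitude 3 µV sinusoid at IAF−5 Hz (random phase
  per segment) — spectrally inside the theta band and uninformative about
  proficiency.
- **Alpha:** an amplitude-modulated sinusoid. During navigation and
  eyes-open rest it sits at IAF+1 Hz — the centre of the alpha-high band —
  so the planted effect lands in a single analysis band (a component
  exactly at the IAF would straddle the alpha-low2/alpha-high boundary).
  During eyes-closed rest it sits exactly at the IAF with a 3× amplitude
  boost, which is what the IAF estimator consumes. Base amplitude is 6 µV
  times a regional profile (occipital 1.5, parietal 1.2, frontal 0.8,
  temporal 0.25, central strip 0.6), jittered per region (U[0.7, 1.3]) and
  per channel (U[0.8, 1.2]) per participant. The AM envelope mixes a weak
  shared modulation (depth 0.1) with a stronger channel-specific one
  (depth 0.5), on ~2 s knots so the AM sidebands stay within ±0.5 Hz of the
  carrier. Partial inter-channel coherence matters: perfectly coherent
  channels would be mutually redundant copies, and the mRMR redundancy
  penalty would then deflect most picks to noise features.
- **The planted effect:** a latent proficiency trajectory `p(t)` — logistic
  in trial index, ≈0 at trial 1 and saturated by `plateau_block` (default
  7 of 10) — drives everything. *Responders* scale the alpha amplitude by
  `1 + (g−1)·p(t)` with effect size g (`alpha_effect_size`, default 2, i.e.
  a doubling of upper-alpha amplitude from the naive to the proficient
  state; the magnitude of the real effect is not known, so g is the single
  free "strength" knob and the validation sweeps it from 2 up).
  *Non-responders* are flat (`gain 1`) or, for a configurable half of them,
  decreasing (`g − (g−1)·p(t)`), mirroring the minority of trainees whose
  upper-alpha power falls across training.
- **Behavior:** certainty ratings follow `floor + (ceiling−floor)·p(t)`
  plus N(0, 1) noise, rounded and clipped to 1–10; completion excess falls
  from 100% to 10% over ideal along `1 − p(t)` plus N(0, 8%) noise, with
  times clipped to [5 s, 180 s]. Ideal times are U[30, 60] s per trial.

Determinism: a `numpy.random.SeedSequence` tree keyed on the cohort seed
(and, in classification, on participant/run/permutation indices) makes
every output a pure function of its configuration.

What the generator does *not* model: eye-blink/EMG artifacts, electrode
drift, re-referencing, event-related dynamics within a trial, IAF drift
within the session, or any spatial mixing beyond static regional gains.
Passing tests therefore demonstrate that the pipeline recovers a planted
amplitude effect under realistic 1/f noise and inter-individual variability
(IAF, spectral slope, regional gains) — not that the classifier would reach
any particular accuracy on real EEG.

## Numerical choices

- **Filters:** linear-phase FIRs (Hamming `firwin`), ~1 Hz transition for
  the 1–50 Hz band-pass and 0.5 Hz for the 2 Hz analysis bands, applied via
  FFT convolution on reflection-padded signals with the group delay
  compensated exactly (zero-phase overall). The production path fuses the
  band-pass, band filters and analytic signal into one FFT per session;
  it matches the sequential reference path (`bandpass_1_50` →
  `filter_hilbert_power`) except for the finite-length edge treatment of
  the analytic signal, whose slowly decaying tails leave a residual well
  under 1e-2 z-units (tested).
- **Resampling:** polyphase 500→256 Hz (64/125); segment boundaries remap
  with floored starts and ceiled ends so no boundary sample is lost
  (adjacent segments may then share one sample, which the floor-based
  epoching ignores).
- **mRMR:** the MID (difference) form with 3 equal-frequency bins is the
  default; the variant choice and bin count are config options. A practical
  consequence of MID worth knowing: once several class-driven features are
  selected, further class-driven features have redundancy comparable to
  their relevance, so late picks can drift to uninformative features. On
  planted-effect cohorts the alpha-high band is reliably the modal source
  of selections (~60–70%), with the temporal region nearly absent.
- **Degenerate inputs:** zero-variance normalization baselines, flat
  8–15 Hz spectra, single-class training pools, sub-1 s trials and
  non-divisible trial/block counts all raise typed errors (or, for short
  trials, drop to zero epochs with a warning) rather than propagating NaNs.
- **EDF:** cohorts are written as plain 16-bit EDF (1 s records, per-channel
  symmetric physical range in µV; quantization ≤ range/32767) plus a
  sessions CSV carrying exact segment sample indices and behavior. Reading
  uses MNE's EDF parser, so the round trip is checked against an
  independent implementation.

## Problem sizes used in validation

The `full` preset reproduces the complete design (15 × 60, 100 runs, 1000
permutations) and is hours-scale. The test suite and the reproduction
script run the `desk` preset — 6 participants × 20 trials in 4 blocks of 5,
30 s baselines, 8–12 s ideal times, 10 runs, 200 permutations where a null
is needed — chosen so a complete cohort analysis takes tens of seconds
while every count that is checked exactly (164 features, 10 selections per
run, class sizes) is preserved, except that 20 trials label 2 trials per
class instead of 6. The headline recovery check runs 20 independent
desk-scale responder cohorts (effect size 2) and requires block-1 NI below
0.3, final-block NI above 0.7 and a significantly positive mixed-model
slope in ≥ 90% of them; flat-gain cohorts must show chance-level nulls and
no slope.

## Known limitations

- The mixed model uses a random intercept only; random slopes are not
  implemented.
- The per-trial NI confidence band is computed across runs (not across
  epochs); with a single run it collapses to the point estimate.
- The effective/ineffective grouping uses permutation significance only.
- The 41-channel subset ships as an editable CSV; the default membership is
  one reasonable reading of a 64-channel cap layout and can be swapped
  without code changes (the only hard constraints are the count and the
  central-strip exclusion).
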