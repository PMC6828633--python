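# Methods

This document describes the decoding model, the retraining protocols, the
synthetic data generator and the numerical design decisions behind
`coadaptbci`.

## 1. Protocol and timing

Each trial is 8 s long, sampled at 256 Hz (2048 samples), with trial start
at t = 0:

| Event | Time |
| --- | --- |
| Fixation / baseline | 0 – 3 s |
| Cue (class instruction) | 3 s |
| Imagery period | 3 – 8 s |
| Feedback bar shown from | 4.25 s |
| CSP training epoch | 4.75 – 7.75 s (3 s) |
| LDA training feature | 1-s window ending at 5.5 s |
| Accuracy evaluation window | [4, 8) s |

Classes are right-hand (label 0) vs. both-feet (label 1) motor imagery. A
full session holds 190 trials per class (TPC) in runs of 10 TPC; classes
are balanced within every run.

## 2. Decoding pipeline

**Filterbank.** 15 Butterworth bandpass filters of order 8 (designed as
4th-order prototypes, giving 8 poles in bandpass form), applied causally in
second-order-section form: seven overlapping mu bands 6–8, 7–9, …,
12–14 Hz and eight overlapping beta bands 14–19, 17–22, …, 35–40 Hz.
All filters are verified stable at design time.

**Shrinkage CSP.** Per band, class covariance matrices are averaged over
trials of the 3-s imagery epoch and shrunk toward a scaled identity
`(tr C / d) I`. The shrinkage intensity is analytic (Ledoit–Wolf style):
the ratio of the variance of the mean covariance estimate to its distance
from the target, clipped to [0, 1], treating per-trial covariances as
i.i.d. observations. The composite covariance is whitened and the whitened
hand-class covariance eigendecomposed; the 3 filters with the largest and
the 3 with the smallest generalized eigenvalue are retained (6 per band).
The implementation is hand-written (whiten-then-rotate); the test suite
verifies it against `scipy.linalg.eigh(C1, C1 + C2)` to 1e-8.

**Features.** Log-variance of each CSP projection over the trailing 1-s
window: 15 bands × 6 projections = 90 features. A small floor (1e-10)
guards the logarithm. Streaming evaluation uses cached window second
moments (`wᵀSw − (wᵀm)²`) so each of the 16 updates per second is O(d²)
rather than O(d·n).

**Shrinkage LDA.** Pooled class-centered covariance shrunk toward
`(tr S / d) I` with the analytic Ledoit–Wolf intensity
(scikit-learn's `ledoit_wolf_shrinkage`, `assume_centered=True`).
Weights `w = Σ̂⁻¹(μ_feet − μ_hand)`, bias at the midpoint. Per-class linear
discriminants `g_k(x) = μ_kᵀΣ̂⁻¹x − ½μ_kᵀΣ̂⁻¹μ_k` feed the softmax. At
zero shrinkage the classifier matches classical LDA
(`sklearn` `lsqr` solver, weight cosine ≥ 0.999 in tests). A score of
exactly 0 (tie) classifies as hand.

**Stream classifier.** From 1 s of within-trial data onward, a class score
is emitted every 1/16 s (16 Hz), yielding 113 outputs over an 8-s trial.
The feedback bar shows the fraction of correct classifications in the
trailing second, hidden below 50% (50% inclusive shows).

## 3. Outlier rejection

Candidate training trials are screened on a 3–35 Hz bandpass **copy**
(order-4 Butterworth; the decoding signal path is untouched):

- **Amplitude**: any sample beyond ±125 μV rejects the trial
  unconditionally.
- **Joint probability**: per-trial mean negative log-likelihood of its
  sample amplitudes under the pooled empirical amplitude distribution of
  all accumulated candidates (histogram with fixed ±1000 μV edges, 256
  bins). Trials more than 4 SD above the population mean are rejected
  (one-sided — only *improbable* trials are artifacts).
- **Kurtosis**: channel-averaged excess kurtosis more than 4 SD from the
  population mean rejects (two-sided).

Per-trial histogram counts are cached so each incremental screening is
O(bins), not O(samples). A zero-variance statistic flags nothing.

## 4. Recurrent retraining

Both policies fit the first decoder once 10 accepted TPC are available and
refit at an absolute per-class threshold lattice 10, 15, 20, … TPC
(every 5 new TPC). Refits use all accepted trials so far; new decoders are
hot-swapped only between trials.

**Supervised**: true labels throughout. On a clean 190-TPC session this
yields 37 refits (thresholds 10 … 190).

**Semi-supervised**: identical until 40 TPC (80 trials) have been
*observed* — counted label-free so the switch itself never reads a label.
After the switch, each feedback trial is assigned an **artificial label**:
per classifier output, class probabilities are computed by softmax over the
two discriminants (Eq. 1 style); the trial's confidence is the **peak class
probability** over the feedback period and its artificial label is the
class achieving that peak. When 5 pending trials per artificial class have
accumulated (and at least 4 total), the batch passes a **quartile gate**:
only trials whose peak probability lies within [Q1, Q3] of the batch
(inclusive, `np.quantile` linear interpolation) survive; both
low-confidence (near-boundary) and suspiciously overconfident trials are
discarded permanently. Gating is applied once per trial
("gate-once"): survivors are banked and count toward the 5-per-class refit
quota; they are never re-gated against later batches. A refit consumes the
40-TPC true-label calibration pool plus all banked artificial-label
survivors. Because gating discards roughly half of each batch, refits are
correspondingly rarer (17 vs. 37 on the reference session).

A failed refit (degenerate covariance) leaves the current decoder in place.

## 5. Synthetic ERD sessions

The generator produces what the decoder needs and nothing more:

- **Background**: 1/f (pink) noise on all 13 channels (FC3, FCz, FC4, C5,
  C3, C1, Cz, C2, C4, C6, CP3, CPz, CP4), RMS 5 μV, FFT-shaped.
- **Idle rhythms**: band-limited filtered-noise mu (8–12 Hz, 7 μV RMS) and
  beta (16–24 Hz, 3.5 μV RMS) oscillations at C3, Cz and C4.
- **ERD**: during the imagery period [3, 8) s, hand trials attenuate the
  C3 rhythms and feet trials the Cz rhythms by a fractional depth
  (default 0.25), with 0.5-s raised-cosine ramps.
- **Volume conduction**: a fixed row-normalized `I + 0.25·adjacency`
  mixing over the electrode grid, so spatial filtering is actually needed.
- **Artifacts** (optional): 0.5-s Hann-windowed 8-Hz bursts of settable
  amplitude on random channels, for exercising the rejection stage.

The default depth 0.25 was chosen so a full supervised session decodes at
~85% mean / ~89% peak accuracy — the realistic mid-range between chance
(depth 0 decodes inside the 54.3% chance band) and ceiling (depth 0.7
exceeds 99% peak). The generator does **not** emulate non-stationarity,
user learning, eye/muscle artifacts with realistic spectra, or
cross-subject variability; it is an effect-size-controlled testbed, not a
forward model of EEG.

## 6. Evaluation

- **Accuracy time-course**: per classifier output time, averaged over
  feedback trials; summary metrics are the curve peak and its mean over
  [4, 8) s.
- **Chance level**: upper bound of the adjusted Wald binomial interval at
  p = 0.5 — add two pseudo-successes and two pseudo-failures, giving
  `50 + 100·z₀.₉₅·sqrt(0.25/(n+4))` percent; 54.3% for n = 360 evaluated
  trials, α = 0.05. Verified in tests against a 10⁶-replicate Monte-Carlo
  coin-flip oracle.
- **Spectral diagnostics**: small-Laplacian derivations of C3/Cz/C4
  (center minus mean of 4 orthogonal neighbours), condition-averaged Welch
  PSD with 1-s non-overlapping segments over the feedback period, in dB.

## 7. Numerical and design decisions

- Estimator-shaped components (`ShrinkageCSP`, `ShrinkageLDA`,
  `MotorImageryDecoder`) follow the scikit-learn fit/predict convention;
  the protocol machinery (retraining, replay, rejection) is procedural.
- Hand-written CSP and sLDA cores with SciPy/scikit-learn used only as
  test oracles, because the shrinkage targets and selection rules here are
  not exposed by the library implementations.
- All randomness flows through explicitly seeded `numpy` generators;
  replaying a session draws no random numbers at all, so results are
  bit-identical across runs.
- The supervised refit schedule is an absolute threshold lattice rather
  than a relative "+5 since last refit" counter, so rejected trials delay
  but never skip a scheduled refit.
- The quartile gate population is the current pending batch (not the
  historical pool), and each trial is gated at most once; this keeps the
  gate's selectivity constant as the pool grows.
- HDF5 (`h5py`) is used for sessions, models and replay results; EDF/GDF
  import is optional via MNE.
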