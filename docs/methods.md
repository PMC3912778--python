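# Methods

This note records the model behind `ehgkit`, the parameters that matter,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Signal model and preprocessing

Surface EHG concentrates its energy between roughly 0.1 and 4 Hz, with the
"uterine specific" component of contractions between 0.34 and 1 Hz; below
0.34 Hz respiration interferes, above 1 Hz the signal-to-noise ratio of the
uterine component collapses while ECG and motion artifacts dominate. The
chain is therefore: 5th-order Butterworth band-pass 0.1–4 Hz, downsampling
to 20 Hz, bipolar derivation (B1 = M1−M5, B2 = M5−M3, B3 = M4−M5,
B4 = M5−M2) to cancel common-mode interference. Only bipolar channels are
analysed.

Numerical choices:

* **Zero-phase filtering.** The Butterworth filter is applied
  forward-backward (`sosfiltfilt`). Phase handling is an open design
  point; zero-phase was chosen because segment boundaries later become
  timestamps, and a causal filter would bias every onset by the group
  delay. The effective magnitude response is the squared one-pass
  response (the stop band is attenuated twice as fast as the nominal
  order suggests).
* **Downsampling.** Integer ratios use plain sample picking (valid
  because the signal is already limited to 4 Hz, far below the new 10 Hz
  Nyquist); non-integer ratios fall back to polyphase resampling.
* **Edge transients.** Filters run with default padding; nothing is
  trimmed, but envelopes expose `trusted_mask()` flagging the first and
  last 30 s as untrusted rather than silently deleting them.

## TOCO-like envelopes

Two estimators over 30 s windows stepped 0.25 s on the 0.34–1 Hz
component: windowed RMS, and the unnormalized first spectral moment
(UFM) Σ f·P[f].

* **Timestamping.** Envelope values are assigned to the window *center*;
  the alternative (window start) would bias all onsets early by 15 s.
* **UFM normalisation.** Bin powers are periodogram density × bin width,
  so a pure tone of power P at f₀ contributes f₀·P independent of the
  Hamming taper's noise bandwidth (summing `scaling='spectrum'` bins
  would overcount tones by that factor, ≈1.36 for Hamming).
* **UFM band.** The moment is summed over 0.34–1 Hz. Because the input
  is pre-filtered to that band, summing the full axis would be nearly
  identical; the band sum makes the restriction explicit.

## Baseline and segment detection

The baseline of an envelope is the mean of the lowest 10% of values in a
centered 4-minute moving window (windows truncated at the record edges;
"lowest 10%" = `floor(0.1·n)` values, minimum 1). Detection is two-pass:

1. candidate windows = maximal runs with envelope > 2× baseline;
2. each candidate is trimmed to where the envelope also exceeds
   baseline + 25% of *that window's own* peak excursion above baseline;
   surviving runs of ≥ 30 s become segments.

The referent of the 25% amplitude rule is genuinely ambiguous; we
evaluated an alternative reading (25% of the envelope excursion within the
4-minute baseline window) and rejected it because a single very large
artifact then suppresses moderate contractions up to two minutes away —
on simulated recordings this cost several structural misses per ten
recordings. The per-window reading keeps both criteria scale-free
(detection is exactly invariant under positive rescaling of envelope and
baseline) and decouples neighbouring events. The rule lives in one small
block of `detect_segments` so other readings can be swapped in.

Boundaries are taken directly from threshold crossings — no hysteresis, no
padding. The two envelope methods give slightly different onsets/offsets;
exact edges are not load-bearing downstream.

Ground-truth matching (simulation only): a segment is labeled by the event
it overlaps most (temporal IoU ≥ 0.3, restricted to events touching the
segment's electrode pair). Any qualifying artifact wins over a
contraction — a window containing both is artifacted, since the artifact
contaminates every feature of that window. Artifact events mostly
contained inside a longer segment also qualify, for the same reason.

## Features

Eleven features per segment, computed on the 0.1–4 Hz, 20 Hz bipolar
slice. Parameters and conventions:

| feature | definition | choices |
| --- | --- | --- |
| E1, E2, E3 | band energy fractions 0.1–0.3 / 0.3–1 / 1–4 Hz | single Hamming periodogram of the whole segment (no Welch averaging); bands partition the denominator so E1+E2+E3 = 1 exactly |
| σ_x, RA, κ | SD, (max−min)/σ_x, kurtosis | κ is the *non-excess* fourth standardized moment (Gaussian → 3), the usual convention in artifact-detection work |
| MD_bs, MD_x | max one-sample derivative over σ_baseline / σ_x | baseline reference = EHG samples whose envelope value falls in the lowest decile of its 4-minute window, concatenated; ≥ 30 s required |
| R_RMS | RMS(segment)/RMS(baseline) | same reference |
| En | sample entropy, m = 3, r = 0.15 | r interpreted as 0.15 × segment SD (the universal SampEn convention; a fixed-amplitude reading is the other possibility), Chebyshev distance, self-matches excluded; A = 0 ⇒ +inf, not an error |
| Tr_z | surrogate z-score of Tr = ⟨(x_i−x_{i−τ})³⟩ | τ = 1 sample at 20 Hz (exposed as a parameter); 100 IAAFT surrogates |

IAAFT surrogates iterate spectrum adjustment and rank remapping (max 100
iterations or relative spectral error < 1e-8), ending on the amplitude
step, so every surrogate is exactly a permutation of the original values
and its spectrum matches to well under 5% relative L2 error. This is the
null of a monotonically transformed linear Gaussian process — the standard
null for the time-reversibility test.

Undefined features (zero variance, zero band energy) raise a structured
`FeatureError` naming the feature; the pipeline logs and excludes such
segments rather than imputing sentinels.

## Classification

Positive class = artifacted (the minority class in realistic data; this
is what makes sensitivity/NPV the harder metrics). LDA and QDA come from
scikit-learn; the SVM is an RBF-kernel SVC behind a standardising scaler
(discriminant analyses are affine-invariant and get none). When a class
covariance is singular (few segments, collinear features) the QDA falls
back to an explicit ridge variant (Σ + ε·I, ε = 1e-6·max(tr Σ/d, 1)) and
LDA to the lsqr/shrinkage solver — regularisation only on demand, logged.

Model assessment: 50 repetitions of a random *stratified* 50/50 split,
training on each half and evaluating on the other. Stratification is an
addition over plain random splitting; at realistic class sizes it prevents
degenerate single-class folds. Reported mean ± SD are repetition-level;
fold-level values are retained in the `CVReport`. SVM hyperparameters
(C, γ) are optimized by Nelder–Mead simplex over (log₁₀C, log₁₀γ) on
cross-validated training error, starting at C = 1, γ = 1/d.

Sequential forward selection greedily adds the feature minimising repeated
two-fold CV error and stops when no candidate improves by more than
0.1 percentage points — the tolerance keeps pure-noise features out. The
seven-feature preset `DEFAULT_ARTIFACT_FEATURES` (E3, RA, κ, MD_bs, MD_x,
En, Tr_z) is shipped as a convenient starting subset, but SFS should be
re-run on any new dataset. `holdout_test` guards against leakage by
requiring disjoint `group_id` (recording/subject) sets.

## The simulator

`synthesize_recording` emulates, per seeded config:

* baseline: 1/f-shaped Gaussian noise low-passed at 4 Hz — the bandwidth
  the preprocessing passes;
* contractions (default 12/h, 40–90 s): Hann-tapered 0.34–1 Hz bursts.
  The taper avoids creating step artifacts at contraction edges. Channels
  mix a shared carrier with independent ones (50/50 power), because a
  perfectly common-mode burst would be cancelled by bipolar derivation —
  partial inter-electrode correlation is also the physiological picture.
  `snr_db` (default 14 dB) fixes the channel-average ratio of burst to
  baseline power inside the band; per-channel gains vary ±25%.
* artifacts (default 8/h): *pulses* — trains of large spikes with an
  exponential electrode-recovery tail (the tail makes them
  time-asymmetric, as real movement spikes are); *steps* — sharp baseline
  shifts with a slow sag, 15–30 s (a band-passed boxcar much longer than
  the 30 s envelope window would split into two edge bumps; brief
  repositioning episodes are also the physical picture); *hf_bursts* —
  broadband bursts with 85% of their energy in 1–4 Hz and a 15%
  low-frequency skirt (a brick-wall 1 Hz cutoff would make bursts
  invisible to the 0.34–1 Hz envelope at any plausible amplitude, which
  real broadband artifacts are not). Amplitudes (60×/45×/30× the
  baseline SD) are free parameters — no amplitude statistics exist for
  clinical artifacts — chosen so artifact events stand ≥ 3× above the
  envelope baseline, i.e. clearly detectable, as vigorous motion
  artifacts are in practice.
* optional interference: respiration-like (slowly wandering 0.20–0.34 Hz
  tone) and ECG-like (quasi-constant ~1.2 Hz spike train), off by
  default.

Events are scheduled with a ≥ 40 s mutual gap. All randomness flows from
one `numpy.random.Generator`; a fixed seed reproduces recordings
bit-exactly.

**What passing on this bench does and does not show.** The simulator
captures the spectral geometry, amplitude scale and temporal asymmetry of
the signal classes, so it validates the *mechanics* of the chain:
filters, envelopes, thresholds, feature math, surrogate null, CV
protocol. It does not capture inter-patient amplitude variability,
electrode impedance drift, fetal ECG breakthrough, artifact waveform
diversity, or expert-label noise — classifier accuracies measured here
are upper bounds that say nothing quantitative about clinical
performance.

`simulate_labeled_windows` builds balanced window-level datasets directly
(contraction cores sliced from bursts that outlast the window; artifacts
co-occurring with a contraction half the time, labeled artifacted), which
is how training tables of arbitrary size are produced without simulating
hours of recording.

## Problem sizes used by the test and acceptance suites

Oracle comparisons use 50 random series of N = 600 (sample entropy,
1e-12 agreement against an independent template-counting implementation)
and 100 random envelopes (detection against per-sample thresholding).
Surrogate calibration uses 20 AR(1) and 20 sawtooth-plus-noise series,
100 surrogates each. Detector recovery uses ten 30-minute recordings
(~100 events). The directional feature check uses 120 labeled windows
with 100 surrogates each. `scripts/acceptance.py` uses four 30-minute
recordings and 80 labeled windows. These sizes give stable statistics at
interactive runtimes; all scale linearly if increased.

## Known limitations

* The 25% detection rule is one reading of an ambiguous specification;
  alternatives change segment edges by seconds.
* Segments are detected per channel and per envelope method; there is no
  cross-channel fusion of candidate windows.
* The UFM envelope is not calibrated to pressure units; envelopes are
  relative traces only.
* SampEn of short, highly regular segments can be +inf (no m+1 matches);
  such windows are excluded from training tables.
* The simplex SVM search optimizes a noisy CV objective; with few
  windows the returned (C, γ) can sit on a plateau. Results in this
  package use it with fixed internal split seeds, which makes it
  deterministic but still a local search.
* Real-time/streaming operation is out of scope; the chain is batch.
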