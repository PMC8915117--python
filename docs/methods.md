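# Methods

This note documents the models, algorithms and design choices behind the
package, in the order the pipeline applies them.

## Problem setting

Single-lead ECG records identify people: the amplitudes of the P, QRS and T
waves and the intervals between their landmarks are stable within a subject
and variable across subjects. The pipeline turns a raw sample stream into an
identity decision in four stages: denoise, delineate, featurise, classify.
All stages operate at a nominal sampling rate of 360 Hz (configurable).

## WT-UKF denoising

The record is decomposed to 8 scales with the Mallat cascade (db8 mother
wavelet, symmetric boundary extension). At 360 Hz the nominal band of the
detail coefficients at scale *j* is [fs/2^(j+1), fs/2^j]: 90–180 Hz at scale
1, 45–90 Hz at scale 2, and the scale-8 approximation covers 0–0.703 Hz.
(Quoted figures elsewhere sometimes print 0.781 Hz for the deepest band,
which corresponds to a 400 Hz rate; this package always derives bands
analytically from fs.)

Three bands are treated:

* **A8 (0–0.7 Hz) is zeroed** — baseline wander (respiration, electrode
  drift, nominally ~0.3 Hz) lives here. A side effect is that the ECG's own
  sub-0.7 Hz content (mostly its DC offset and slow beat-envelope) is also
  removed; wave *differences* are unaffected, which is why the feature set
  uses amplitude differences only.
* **D1 (90–180 Hz) is zeroed** — mostly broadband noise; ECG energy there is
  negligible.
* **D2 (45–90 Hz) is smoothed by an unscented Kalman filter** rather than
  threshold-shrunk. Powerline interference (50/60 Hz) falls in this band,
  but so does genuine QRS edge energy; shrinkage attacks both, whereas a
  random-walk UKF tracks the slowly structured QRS content while averaging
  out the oscillatory interference.

The UKF state model on the D2 sequence is a scalar random walk
(x_{k+1} = x_k + w, y_k = x_k + v). The observation-noise variance R is
estimated from the coefficient sequence by the robust wavelet-domain rule
(MAD/0.6745)², and Q = 0.01·R by default; smaller Q/R smooths harder. Sigma
points use the standard scaled parameterisation (α = 1e−3, β = 2, κ = 0);
the initial state is the first observation with covariance R. The filter is
run once forward over the whole record's coefficient sequence. On any
linear-Gaussian system this implementation reproduces the classical Kalman
recursion to ~1e−9, which the test suite asserts.

Denoising quality is summarised by SNR = 20·log10(A_signal/A_noise) with RMS
amplitudes (a peak-amplitude variant is available) and by RMSE against the
clean reference. Classical per-scale soft-threshold shrinkage (universal
threshold with a heuristic universal/SURE hybrid, or pure SURE) is provided
as the comparison baseline; on records contaminated with 0.3 Hz + 50 Hz
sinusoids the WT-UKF pipeline attains higher SNR and lower RMSE than either,
chiefly because shrinkage cannot remove in-band baseline wander at all.

## Fiducial delineation

QRS detection follows the dyadic quadratic-spline wavelet scheme: an
undecimated (à trous) transform with the spline filter pair
h = [1,3,3,1]/8, g = [2,−2] yields smoothed-derivative channels at scales
2^1..2^4. A QRS complex appears at scale 2^2 as a pair of opposite-sign
modulus maxima; the R peak is the signal maximum near the zero crossing
between them.

Candidate modulus extrema must clear max(0.3 × local 2-s RMS, 0.15 × record
peak modulus). Extrema are chained into groups with a 45 ms gap rule — the
slope extrema of one QRS are closer than that, while P/T lobes and
inter-wave gaps are wider — and each group's dominant positive/negative pair
is a QRS candidate. A two-level adaptive threshold in the style of classical
QRS detectors (running QRS-level and noise-level estimates, decision
boundary a quarter of the way up) rejects the smaller P/T pairs, and a
200 ms refractory rule keeps the larger of two near-coincident candidates.

Q and S are the troughs nearest R, found by walking down each flank (on a
5-sample-smoothed copy, so a one-sample noise notch cannot stop the walk)
within 80 ms windows. P is sought in [R−300 ms, R−60 ms] (truncated at Q),
T in [S+60 ms, R+450 ms]; each wave's peak is refined to the scale-2^4
transform zero crossing between its two modulus lobes, which is much more
stable than an argmax on a flat noisy crest. A wave is declared present only
if its lobe modulus exceeds 1.5 × the record's median scale-2^4 modulus
(the noise floor); beats failing this, or any window/ordering constraint,
are dropped and logged rather than imputed. The threshold sits between the
absent-wave floor (≈1× median) and the weakest genuine P lobes (≈2.2×)
observed on generator cohorts.

**Onset/offset convention.** The package defines a wave's onset and offset
as peak ± 2.5 wave widths (σ of a Gaussian-shaped wave). The width is read
off the transform itself: the modulus lobes sit one *effective* width from
the peak, where the effective width folds in the transform kernel's own
smoothing width (≈4.6 samples at scale 2^4, computed from the filter bank's
impulse response); deconvolving that gives the wave's width. Each wave uses
the lobe on its far side from the QRS — left for P, right for T — because
QRS transform energy can bleed into the near side. Per-beat widths are
winsorised at the record median ± 2 samples: morphology is stable within a
record, so this rejects occasional gross mislocalisation without flattening
genuine beat-to-beat variation (a fully pooled width would give every beat
of a record an identical bit-pattern and thereby leak a record-identity
signature into the features). The T onset is additionally clamped to lie at
or after S, so it can never fall inside the QRS complex.

Detection is invariant to amplitude scaling (all thresholds are relative)
and translation-equivariant up to record edges.

## Features and datasets

Each delineated beat with an R-R successor yields 22 features: 16 intervals
in seconds (R-R to the next beat, R-Q, R-S, R-P, R-T, R-PBegin, R-PEnd,
R-TBegin, R-TEnd, Q-P, Q-PBegin, S-T, S-TEnd, P-T, PBegin-PEnd,
TBegin-TEnd) and 6 amplitude differences in mV (R-Q, R-S, Q-P, S-T,
PBegin-P, TBegin-T), signed first-minus-second. Intervals are
|Δindex|/fs, so they are fs- and amplitude-independent; amplitude
differences are DC-invariant. The last beat of a record is dropped (no R-R
successor).

Datasets are split per subject (stratified) at a configurable training
fraction (default 70/30), and z-score normalisation is fitted on the
training rows only — RBF-SVMs are scale-sensitive, and fitting statistics on
all rows would leak test information.

## One-vs-one RBF-SVM

For k subjects, k(k−1)/2 binary soft-margin classifiers are trained, one per
unordered pair, each on that pair's rows only. The kernel is
K(x,y) = exp(−g‖x−y‖²); the binary quadratic program is delegated to
libsvm via scikit-learn's `SVC`, while this package owns the pairwise
construction, the voting rule and the cross-validation protocol. Prediction
accumulates one vote per sub-classifier; ties break by the largest
accumulated signed decision margin, then by the lowest label, making
prediction deterministic and order-independent. Model selection uses
stratified 3-fold cross-validated accuracy with a fixed shuffle seed.

## IPSO hyperparameter search

The swarm optimises (c, g) on the rectangle c ∈ [2², 2¹¹], g ∈ [2⁻⁴, 2³],
in linear coordinates (reported optima in this problem family are not powers
of two, so a log₂ grid would be needlessly coarse). Reference configuration:
20 particles, 50 iterations, inertia ω decaying linearly 0.9 → 0.4,
learning factors C₁ = C₂ decaying 2 → 0.5, velocity clamped per dimension to
20% of the dimension span, positions clipped to the box. One particle starts
at (c, g) = (10, 2); the rest are uniform in the box with zero initial
velocity.

Before each fitness evaluation a particle mutates with probability 0.1: one
coordinate, chosen fairly, is redrawn uniformly on that coordinate's bounds.
Drawing on the bounds (rather than on [0, 1]) keeps mutants inside the
search box; mutation replaces the particle's current position, not its
personal best. The fitness is the 3-fold cross-validated accuracy of the
OVO-SVM on the *training* split only, so the held-out test beats never
influence hyperparameters. All randomness comes from a single seeded
generator; identical seeds give identical trajectories.

The bundled end-to-end experiment tunes with a reduced swarm (8 particles ×
10 iterations): the cross-validated fitness surface of the synthetic
cohorts is broad and unimodal near its optimum, and the reduced schedule
reliably lands within it, keeping a full experiment around half a minute.
The full 20 × 50 schedule is exercised on a cheap analytic objective in the
tests and is available via `SwarmConfig`.

## Synthetic cohorts

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
subject-specific amplitudes, widths and offsets relative to R; landmark
ground truth is analytic (peaks at bump centres, onsets/offsets at centre ±
2.5 widths — the same convention the detector implements). Subject templates
are drawn uniformly from physiologically ordinary ranges (R amplitude
0.8–1.6 mV, P 0.1–0.25 mV, T 0.2–0.5 mV, P-to-R offset 0.14–0.20 s, T
offset 0.22–0.30 s, heart rate 50–75 bpm); within-subject jitter (4%
relative on amplitudes, 4 ms on offsets, 2% on R-R) is several times
smaller than the between-subject spread, so classes are
separable-but-overlapping. Noise is additive: a 0.3 Hz baseline sinusoid
(default 0.2 mV), a 50 Hz powerline sinusoid (default 0.1 mV), and white
noise (default 0.01 mV SD), each with a seeded random phase.

What the generator does *not* emulate: non-sinusoidal/wandering-frequency
baseline drift, motion artifacts, ectopic or otherwise pathological beats,
respiration-modulated amplitudes, multi-lead geometry, and asymmetric or
biphasic wave shapes. Passing tests therefore demonstrate the pipeline's
internal consistency and its behaviour under the modelled contaminants, not
clinical-grade performance on archived recordings; on the arrhythmia-rich
public databases the published numbers for this family of methods are a few
percent below the near-perfect accuracies reached on these clean synthetic
cohorts.

## Numerical choices and degenerate inputs

* Wavelet roundtrip is exact to ~1e−15 relative; perfect reconstruction is
  asserted at 1e−8.
* Parseval bookkeeping is exact under periodization boundary handling;
  symmetric padding (the default, chosen to minimise edge ringing on
  biosignals) adds edge-coefficient energy and is excluded from that check.
* An all-zero or too-short record yields an empty R list, not an error; a
  record shorter than the decomposition depth raises immediately.
* The UKF symmetrises the covariance after every update and raises (with
  the step index) if the state goes non-finite.
* Sub-classifier vote ties are broken by margin, then lowest label.
* The swarm raises on non-finite fitness, reporting the position.

## Known limitations

* The absent-wave test (lobe modulus vs. noise floor) is a one-sided
  guarantee: with a wave truly absent, a minority of beats can still pass
  when neighbouring-wave tails produce a credible lobe; the test suite
  asserts majority rejection, not totality.
* Q/S are defined as flank troughs; notched (fragmented) QRS morphologies
  would need the multi-extremum logic this package does not implement.
* Records are processed independently; there is no cross-record template
  adaptation.
* CSV is the only record format; interoperability with archived waveform
  databases requires converting to CSV first.
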