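# Methods

## Pipeline overview

The analysis chain is: (1) preprocessing — 50-Hz notch, 3–50 Hz
band-pass, common-average reference, downsampling 2,000 → 500 Hz, and
extraction of 2.5-s epochs starting 1 s before each right-paw-contact
(RC) event; (2) sliding-window phase-lag index (PLI) over a 250-ms /
50 %-overlap grid (19 windows per epoch); (3) collapse of the window
axis to the four gait phases; (4) weighted graph metrics and condition
statistics; (5) locomotion-condition classification from connectivity
features.

## Phase-lag index

PLI is the absolute mean of the signum of the wrapped instantaneous
phase difference, with sign(0) = 0.  Numerical choices:

* the analytic signal is computed once per full 2.5-s epoch and then
  sliced into windows, so Hilbert edge artifacts are confined to the
  epoch boundaries instead of recurring at every window boundary;
* the phase difference is wrapped to (−π, π] before the signum (the
  sign of an unwrapped difference is meaningless); at exactly ±π the
  wrap convention assigns +π, a measure-zero tie-break that matters
  only for analytically anti-phase inputs;
* PLI is invariant to per-channel amplitude scaling by construction;
  the test suite asserts this and the equality of the vectorized
  implementation with a literal one-sample-at-a-time evaluation to
  1e−12.

## Window ↔ gait-phase geometry

At 500 Hz the 250-ms window is 125 samples and the 50 % step is 62.5
samples; window start indices are `round(62.5·k)`.  Even-indexed windows
therefore start exactly at multiples of 125 samples, which makes three
windows (indices 0, 2, 4) tile the 750-ms preparation phase without
overlap and one window each coincide exactly with the three 250-ms
walking sub-phases (indices 6, 8, 10).  The preparation-phase matrix is
the mean of windows 0/2/4; each walking phase takes its coincident
window.  Straddling windows enter only the time-resolved global-metric
curves, never the phase matrices.  The collapse refuses any grid other
than the standard one rather than guessing an alignment.

## Preprocessing choices

The filter family is a 4th-order Butterworth band-pass and a 2nd-order
IIR notch (quality factor 30), both applied forward–backward: a causal
filter would add a frequency-dependent phase shift, which is exactly the
quantity PLI is built on.  Zero-phase filtering and the common-average
reference are both linear and time-invariant per channel, so their order
does not matter (asserted in tests); the implemented order is notch →
band-pass → CAR → downsample.  Downsampling is plain decimation, valid
because the 3–50 Hz band-pass leaves no content above the 250-Hz target
Nyquist.  Epoch windows are half-open, `[RC − 1.0 s, RC + 1.5 s)`, with
events snapped to the nearest sample; epochs that would cross a
recording edge are skipped and counted.  An artifact-removal hook
(`cleaner=`) occupies the position a manual ICA component rejection
would have in a lab workflow; it defaults to a no-op, since visual
component screening cannot be faithfully automated and the synthetic
data contains no such artifacts.

## Graph metrics

Brain Connectivity Toolbox conventions throughout: edge distance 1/w,
Dijkstra shortest paths; global efficiency averages 1/d over ordered
pairs with disconnected pairs contributing 0; characteristic path
length averages d over connected ordered pairs only (the count of
disconnected pairs is reported); transitivity and clustering use Onnela
triangle intensities — geometric means of triangle weights after
normalizing the matrix by its maximum — so both are invariant to
uniform weight scaling; local efficiency is the global efficiency of
each node's neighborhood subgraph with original weights; eigenvector
centrality is the non-negative unit-norm leading eigenvector by power
iteration (tolerance 1e−10).  Isolated nodes get strength/clustering/
local efficiency 0, never an exception.  Metrics are always computed on
the full weighted matrix; the "keep edges above 50 % of the strongest
connection" threshold is a display convention applied only to exported
edge lists and plots.  The suite cross-checks path metrics against a
Floyd–Warshall oracle, clustering/strength against networkx, and
centrality against a dense eigendecomposition.

## Statistics

Per metric and gait phase, one-way ANOVA compares the per-epoch values
of the three conditions (classic between/within mean-square ratio; the
degenerate all-identical case is defined as F = 0 with a warning rather
than NaN).  Post hoc pairwise comparisons use Tukey HSD — the standard
companion to a one-way ANOVA with three groups; the source analysis
names no post hoc procedure, so this is our choice.  P-values are
reported per comparison and deliberately uncorrected across metrics and
phases, and the output tables say so.  Epochs are treated as exchangeable
(no per-animal random effect is modeled).

## Classification

Feature families and their closed-form dimensions: raw signal
32 × 750 = 24,000 (the −1,000…+500 ms span at 500 Hz, i.e. one full gait
cycle); whole-cycle PLI 32² = 1,024; time-varying PLI 4 × 32² = 4,096;
merged k-phase PLI k × 1,024; one local metric per node per phase
4 × 32 = 128; one global metric per phase 4.  Classifiers are standard
scikit-learn implementations — RBF-kernel SVM (C = 1, gamma scaled),
Gaussian naive Bayes, 5-nearest-neighbors — because the contribution
here is the feature pipeline, not the classifiers.  Features are
standardized with training-fold statistics only.  Cross-validation is
stratified 5-fold; the fold assignment is a function of the labels and
the seed alone, so all families are compared on identical splits.  F1 is
macro-averaged over the three classes (the binary harmonic-mean formula
does not pin down a multiclass convention; macro weights the three
conditions equally).

## Synthetic generator

The generator emulates the statistical structure of the study's
recordings so that coupling recovery and classification can be tested
against a known ground truth:

* **Gait schedule.**  Idealized cycles LC→RO→RC→LO with intervals
  750/250/250/250 ms (the empirical means in the source setting,
  747/238/245/258 ms, are standardized to these values for analysis),
  one condition label per cycle, optional uniform interval jitter
  (default 0).  Conditions are assigned from a caller-given sequence or
  balanced and shuffled.
* **Coupled pairs.**  Each designated channel pair owns a shared
  narrow-band source cos(2πft + W(t)) — carrier 8 Hz, Wiener phase
  drift 2 rad/√s — seen by one channel directly and by the other at a
  fixed lag (default a quarter carrier cycle, 31.25 ms), which centres
  the pair's phase difference at π/2.  The source enters with amplitude
  equal to the coupling strength of the gait phase and condition active
  at that instant, so coupling switches with the schedule.
* **Backgrounds.**  Each channel carries private Gaussian noise
  band-limited to 3–50 Hz at amplitude 1 − (total shared amplitude),
  plus optional white sensor noise (`noise_sigma`, default 0.2 ≈
  SNR 12) and an optional 50-Hz mains tone.  The background is
  broadband *by design*: pre-build Monte-Carlo showed that a
  narrow-band background cannot push the null (uncoupled-pair) windowed
  PLI below ~0.27 — any phase drift fast enough to mix the signum
  inside a 250-ms window broadens the source far beyond the analysis
  band — whereas the band-limited-noise background yields a measured
  null of ~0.21 through the full pipeline, far below the coupled-pair
  level of 0.85–1.0.  Shared sources stay narrow-band so PLI targets
  remain analytically predictable.

Everything is reproducible from the single config seed.  Two stock
coupling layouts ship with the package: `default_coupling_profiles`
(condition differences concentrated in the two late walking sub-phases,
mimicking the reported finding that unexpected-terrain contact
reorganizes somatosensory coupling after RC) and
`recovery_coupling_profiles` (four pairs with Latin-square strength
gradients over {0, 0.3, 0.6, 0.9} across phases, for rank-recovery
checks).

**What the generator does not emulate:** 1/f spectra, physiological
artifacts (EMG, eye movement), inter-animal variability, volume-conduction
mixing beyond the common-average reference, gait-interval variability
(unless jitter is enabled), or any learning across trials.  Passing
recovery and classification tests therefore demonstrates that the
pipeline measures what it claims on signals with known phase-lag
structure — not that the effect sizes seen on real recordings would be
reproduced.

## Problem sizes

Synthetic sessions in the tests and the acceptance script use 10–30
epochs per condition (30–90 epochs total, 2,000 Hz generation), a desk
scale chosen so the whole validation runs in well under a minute; the
source study pooled 1,846 cycles across six animals.  The null-PLI and
type-I-error calibrations use 200+ windows and 2,000 replicates
respectively.

## Known limitations

* Headline empirical numbers from the source setting (e.g. >95 %
  naive-Bayes accuracy on real recordings) are properties of undeposited
  data and are not reproduced here; the package validates geometry,
  estimator correctness, recovery and qualitative trends.
* The EDF writer is minimal (16-bit, one physical range per file,
  microvolt units); EDF reading goes through MNE.
* Eigenvector centrality of an all-zero graph is defined as the zero
  vector; characteristic path length of a fully disconnected graph is
  infinite.
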