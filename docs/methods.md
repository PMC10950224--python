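# Methods

## Problem setting

Heart murmurs are audible signatures of turbulent blood flow and a primary
screening signal in paediatric cardiology. Phonocardiogram (PCG) datasets
usually carry only *weak* labels — a per-recording or per-patient tag such
as "murmur present" — without onset/offset times of the murmur itself.
`heartmil` implements a two-stage approach that (i) learns to *localise*
murmurs from weak labels via multiple instance learning, providing an
inspectable per-sample "murmurness" trace, and (ii) classifies patients into
three murmur classes (Present / Unknown / Absent) and a binary clinical
outcome (Normal / Abnormal) by fusing learned and handcrafted explainable
features.

## Multiple instance learning with softmax pooling

A recording is a bag `B = {x_1, ..., x_T}` of instances; with per-sample
output of a fully convolutional network, one instance is one output sample
and the effective instance extent is learned by the network's receptive
field. A bag is positive iff it contains at least one positive instance.
Instance probabilities `p(x)` are condensed into a bag probability with
softmax pooling,

    P = sum_x p(x) * exp(p(x)) / sum_z exp(p(z)),

which interpolates between mean pooling (stable gradients, but blurs
responsibility) and max pooling (faithful to the MIL assumption, but brittle
and initialization-sensitive): every instance receives weight, the most
confident instances dominate. Two useful consequences are proved in the test
suite as properties: `mean(p) <= P <= max(p)`, and monotonicity — raising
any instance never lowers the bag probability. Pooling is applied to
probabilities (after the sigmoid), not logits; the gradient of `P` w.r.t.
`p_j` has the closed form `w_j (1 + p_j - P)` with `w` the softmax weights,
which the trainer uses directly.

The localiser is a 1D U-Net: five stride-2 downsampling steps, kernel size
5, ReLU activations, nearest-neighbour upsampling with skip connections, and
a single logit per sample. Channel widths default to `4,8,...,24`; the
murmur-vs-heart-sound discrimination is primarily spectral (murmur energy
sits in 200-450 Hz, valve sounds below ~100 Hz), so modest capacity
suffices and keeps CPU training in minutes. Training: binary cross-entropy
on the pooled bag probability, Adam at lr 1e-3 halved every 10 epochs,
fixed input length 2^14 samples (zero-padded; the pooling mask excludes
padding), stratified 20% inner-validation split, early stopping with
patience 10, best model by validation loss. Recordings labelled "Unknown"
are excluded from MIL training.

### Postprocessing and the explainability score

The murmurness trace is thresholded at 0.6; local maxima with prominence
at least 0.1 are peaks; peaks closer than 60 ms are merged, and each merged
group spans its surrounding above-threshold run. Per recording, *phase
precision* is the fraction of resulting segments overlapping the annotated
murmur phase (systole and/or diastole); a recording without any segment is
reported as `NO_ACTIVATION`, which is the desired outcome on murmur-free
recordings. "Pseudo precision" applies the systolic score to murmur-free
recordings as a bias control.

## Handcrafted explainable features (622)

Extra preprocessing before feature extraction: Schmidt-style despiking
(0.5 s windows; a window whose max |amplitude| exceeds 3x the median of
window maxima has its spike located at the maximum slope of |x| and bridged
by linear interpolation; iterated, max 100 rounds); duration-dependent edge
clipping (cut `c(d) = clamp(3(d-5)/25, 0, 3)` seconds per end); and
envelope clipping that keeps the longest run where the Hilbert envelope
stays below `mean + 2.7 * std`. Two deliberate conventions in the envelope
rule: a zero-variance envelope keeps everything (a strict inequality would
keep nothing), and threshold violations shorter than 250 ms do not break a
run. The second convention matters: on any signal whose loudest content is
sparse transients — which is exactly what S1/S2 are — the envelope peaks sit
several standard deviations above the mean, so a literal reading would cut
every recording down to a single inter-beat gap. Bridging makes the rule
target *sustained* disturbances, which is its purpose. Kept runs longer
than 15 s are additionally trimmed by 5 s per end, as those boundary samples
sit close to the threshold.

Phase segmentation comes from reference annotations when available
(preferred), else from a homomorphic-envelope peak segmenter: peaks at
least 150 ms apart are S1/S2 candidates; the alternation is resolved by the
physiological systole-shorter-than-diastole rule, falling back to relative
loudness (S1 louder than S2) when the two gap classes are within 15% of
each other (they cross near 120 bpm); sound extents are half-height widths
clamped to 60-120 ms. The segmenter rejects signals whose envelope peaks do
not stand out of the background (ratio < 1.4) or whose peak train is
irregular (gap std > 35% of the mean) — pure noise fails both. On clean
synthetic recordings its S1-onset error is ~10 ms (tested against a 40 ms
tolerance).

The 622 features decompose as 5 demographic (age in months, sex, weight,
height, weight/height; missing values are NaN sentinels, never silent
zeros) + 15 duration (average durations of S1, S2, systole, diastole, full
cycle and their 10 pairwise ratios) + 594 time-frequency + 8 shape
features. The time-frequency block applies 33 summaries to each of 18
transformation signals: raw |amplitude|; full-band Hilbert envelope;
spectral centroid; spectral bandwidth; zero-crossing rate; 13 ms windowed
energy; band-limited Hilbert envelopes LF (15-90 Hz), MF (55-150), HF
(100-250), SF (200-450), UF (400-800); and the ratio signals HF/LF, HF/MF,
MF/LF, SF/MF, SF/LF, UF/LF, (HF+MF)/LF (denominator floor 1e-8). The 33
summaries are mean/std/max over the whole signal and per region (S1,
systole, S2, diastole, full cycle — computed per occurrence then averaged
across cycles), plus 15 fixed ratios: six phase-pair mean ratios, four
phase/full-cycle mean ratios and five std/mean ratios. Framewise quantities
use 13 ms frames with half-frame hop, linearly interpolated back to signal
length. Shape features correlate the cycle-averaged systolic and diastolic
envelopes with unit-normalised diamond, plateau, crescendo and decrescendo
templates (values in [-1, 1]); the same templates drive murmur synthesis in
the generator, keeping a single source of truth.

Feature selection trains a gradient-boosted tree classifier (XGBoost, 500
trees of depth 3, lr 0.05, column subsampling 0.05 per tree, row
subsampling 0.8) on the binary murmur task and ranks features by gain
importance; the top 20 are kept and age and weight are always added (they
matter for the outcome head), giving 22. The strong column subsampling is
deliberate: the 622 features are heavily redundant, and without it one good
feature can absorb every split, collapsing the ranking to a single nonzero
importance. Sampling ~30 random columns per tree forces the ensemble to
exercise alternative features, which is what makes gain importance a usable
redundancy-aware ranking here.

## Stage 1: pooling-based encoder (PANN)

Six convolutional base blocks (kernel-5 'same' convolution, batch norm,
ReLU, second convolution, ReLU, dropout 0.1, stride-2 max pooling; channel
progression 16-24-32-40-52-64; ReLU placement is our choice — the block
recipe leaves activations implicit). Adaptive pooling produces exactly 30
values per channel regardless of input length: 15 max-, 10 average- and 5
min-pooled segments. The flattened 1920 values plus a 5-dim one-hot
auscultation location feed a 100-hidden / 20-output fully connected head
and a linear softmax decision layer over (Present, Unknown, Absent).
Training uses class weights proportional to inverse class frequency, Adam
at lr 1e-3 scaled by 0.3 every 30 epochs, stochastic augmentation of each
training batch, and model selection by the mean of training and validation
accuracy. Afterwards the network is frozen and used purely as a feature
generator (20-dim encoding + 3 class probabilities per recording).

Augmentations (each applied independently with probability 0.3, at most 3
per call, in fixed alphabetical registry order): scaling, Gaussian noise,
drop, cutout, shift, linear resampling (heart-rate change), smooth random
time-warping, sine addition, and 0.2-45 Hz band-pass filtering. The
per-augmentation probability is configuration, not ground truth.

## Stage 2: patient-level multitask classifier

Per patient, the fused input is: the 22 selected handcrafted features
averaged over the patient's recordings; per standard location (AV, PV, TV,
MV) the 20 PANN features and 3 probabilities, zero-filled with explicit
mask bits for missing locations; age and weight. With 22 selected features
this gives 22 + 4x23 + 2 + 4 = 120 inputs; the first layer adapts to the
actual width. The network has hidden sizes (123, 492, 246, 20), each
followed by batch norm, leaky ReLU and dropout, and ends in a 3-neuron
murmur head and a 2-neuron outcome head, both softmax. The loss is the sum
of two weighted cross-entropies; per-class weights are inverse relative
class frequencies multiplied by [1, 3, 5] over (Absent, Unknown, Present)
and [1, 5] over (Normal, Abnormal). Inputs are standardised; the scaler is
part of the fitted model.

## Metrics

Weighted accuracy weights true-Present patients 5x and true-Unknown 3x
(numerator `5 m_PP + 3 m_UU + m_AA` over the identically weighted column
totals), so missing murmur-present patients is penalised most. The outcome
cost is the mean per-patient screening cost with four pluggable components
(algorithm, expert review of screened-positive patients, treatment of true
positives, missed diagnoses); defaults follow the published PhysioNet/CinC
Challenge 2022 cost model, which is an external convention these functions
parameterise, not a result of this package. AUROC/AUPRC/F1/accuracy come
from scikit-learn; the test suite cross-checks AUROC against exhaustive
pair counting and weighted accuracy against explicit weighted sums.

## Neural-network implementation

All three networks are implemented directly in NumPy (`heartmil._nn`):
convolutions via stride-tricks + BLAS tensordot, explicit backward passes,
inverted dropout, batch norm with running statistics, and Adam. Every
layer's backward pass is verified against central finite differences in the
test suite. Float32 forward/backward with float64 optimiser state keeps
seeded runs bit-reproducible on a fixed platform.

## Synthetic data: what it emulates and what it does not

The generator produces recordings with exact ground truth: S1/S2 as
exponentially decaying band-limited chirps (S1 60->35 Hz over ~100 ms at
amplitude 1.0; S2 85->50 Hz over ~80 ms at 0.8 — S2 shorter and slightly
higher-pitched), cycle length from the configured heart rate with uniform
jitter, systole fixed at 30% of the cycle, murmurs as band-limited noise
(default 200-450 Hz) amplitude-modulated by a shape template inside the
configured phase with 5% insets, at a configured SNR in dB relative to the
S1 peak. Defects: additive white noise, Poisson spike artefacts, optional
saturation clipping at ±0.95 after peak normalisation. Cohorts assign each
patient 1-4 distinct auscultation locations, consistent demographics
(paediatric ages 12-131 months with allometric height/weight), murmur class
probabilities defaulting to screening-like frequencies (0.19/0.07/0.74),
murmur timing heavily systolic, and outcome labels drawn with
class-conditional abnormality probabilities (0.84/0.63/0.38). "Unknown" is
emulated as a faint murmur (~0 dB) under heavy noise — a deliberately
non-degenerate middle class.

What the synthetic data does *not* emulate: valve acoustics and real murmur
spectro-temporal fine structure, sensor/body-contact artefacts beyond
spikes and saturation, inter-location acoustic differences, respiratory
modulation, and correlated demographics-pathology structure. Passing tests
therefore demonstrate that the algorithms recover planted structure under
controlled conditions — correctness and sensitivity — not clinical
performance.

## Reference experiment sizes

The canonical experiments (in `heartmil.experiments`, reused by the test
suite and `scripts/acceptance.py`) were sized so the whole stack runs in a
few minutes on a single CPU while leaving clear margins: MIL localisation
trains on 240 recordings of 8.192 s (2^14 samples) — 120 systolic murmurs
at +6 dB, 120 murmur-free — for 20 epochs at batch 16, and is scored on
40 held-out recordings; the two-stage experiment trains on 60 patients and
tests on 30 from a separable cohort (Present at 9-12 dB SNR, Unknown at -3
to 0 dB under noise 0.25-0.4, Absent clean), with 30 PANN epochs and 200
stage-2 epochs. The full-scale defaults (batch 128, 10-fold
cross-validation, 100 PANN epochs) remain the configuration defaults of the
respective classes.

## Numerical conventions and degenerate inputs

Half-open, 0-based sample intervals everywhere; TSV seconds are converted
with floor (starts) / ceil (ends), and one-sample collisions from adjacent
floor/ceil boundaries are clamped. Ratio features use a 1e-8 denominator
floor, so global amplitude-scale invariance of ratio features holds to
~1e-4 relative (exact cancellation is spoiled only where a denominator is
comparable to the floor). All-zero signals: no saturation, not noisy by
convention, despike is a no-op. The 10th-order Butterworth band-pass is
realised as a scipy `butter(5, ..., btype="bandpass")` (band-pass designs
double the order) applied forward-backward, trading the causal
phase for zero phase so that murmur timing is preserved. Resampling is
linear interpolation with output length `round(n * out/in)`.

## Known limitations

- The phase segmenter is a peak-based stand-in, adequate for clean signals
  and reference-checked fixtures; it is not an HSMM and degrades under
  heavy noise (by design it then raises rather than guessing).
- Preprocessing is deterministic but not idempotent end-to-end: the
  duration-dependent edge-clip rule cuts again on its own output by
  construction; tests pin determinism and contiguity instead.
- Outcome prediction on synthetic cohorts is intrinsically capped: outcome
  labels are drawn stochastically given the murmur class, so only the
  murmur-conditional base rates are learnable.
- CPU-sized networks: channel widths are deliberately small; scaling up is
  a configuration change, not a code change.
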