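# Methods

`bbscore` implements an automatic scoring pipeline for the Berg balance
scale (BBS), a 14-task clinical balance exam in which a therapist grades
each task 0–4. The input is multichannel wearable-IMU data: eight sensors
(forehead, back, both wrists, ankles and hips), nine channels each (3-axis
acceleration, pitch/roll/yaw, 3-axis accumulated rotation), i.e. 72
synchronous time series at 100 Hz. The pipeline has five stages — EMD
denoising, spectral sampling-rate selection, segment normalization and
padding, same-class k-NN oversampling, and a family of shallow 1D-CNN/GRU
ensemble classifiers scored by stratified 10-fold cross-validation.
Because the clinical recordings this design targets are not public, the
package ships a synthetic-data generator that reproduces their structure,
and every claim the test suite makes is a claim about that generator.

## Synthetic data generator

`bbscore.simulate` emits per-task segments whose channels are sums of:

* a task-specific low-frequency motif — two tones drawn from 0.8–4.5 Hz
  per channel, with canonical per-task phases (segments are
  annotation-aligned, so waveform shape is reproducible up to a small
  phase jitter of 0.4 rad);
* a postural-sway tone at 9.05–9.3 Hz shared by all classes;
* score-dependent mid-band content at 6–8 Hz;
* smooth background noise low-passed at 4 Hz (sigma 0.1);
* optional tremor above 15 Hz scaled by `tremor_level` (default 0.05).

The score s in 0..4 influences the signal through three independent cues,
all gated by the `separation` dial (default 1.0): motif amplitude scales
by (1 + s·separation/4); the leading motif frequency shifts by
s·separation·0.2 Hz; and task duration shrinks by the factor
1/(1 + 0.05·s·separation), emulating faster task completion by stronger
patients. At `separation = 0` every cue collapses and the classes are
identical in distribution, which the test suite verifies with two-sample
tests. Segments taper to rest at both ends (Tukey envelope, alpha 0.6) and
accumulated-rotation channels integrate bounded zero-mean increments, so
trailing zero-padding introduces no artificial discontinuity. Segment
durations are drawn uniformly from 2.5–3.5 s by default so that padding is
exercised nontrivially.

What the generator does *not* model: biomechanical detail of specific BBS
motions, sensor error (bias drift, axis misalignment), inter-subject
kinematic variability beyond RNG phase/duration draws, or non-stationary
artifacts. Tests passing on this generator therefore demonstrate that the
pipeline's machinery is correct and that its statistical procedures behave
as designed — not that clinical accuracy figures transfer.

Determinism: every segment draws from an RNG stream keyed by
(seed, subject, task, …), so corpora are bit-reproducible and independent
of generation order.

## EMD denoising

High-frequency sensor noise is removed with empirical mode decomposition:
the signal is split into up to 10 intrinsic mode functions (IMFs) by
sifting, and the denoised signal is resynthesized from IMFs 1–7 plus the
residue. Sifting uses cubic-spline envelopes through the local extrema,
mirror-extended past both ends (two extrema reflected per side), and stops
on a Cauchy-type criterion Σ(h_prev − h)²/Σh_prev² < 0.05 or after 100
passes; decomposition stops when the residue has fewer than two interior
extrema. Plain EMD rather than an ensemble variant (EEMD/CEEMDAN) keeps
the operation deterministic. Completeness — ΣIMFs + residue equals the
input to 1e-8 relative error — holds by construction and is asserted over
100 random signals.

Two choices the procedure leaves open are resolved as follows. First, the
residue is always added back: discarding it would destroy the signal's
baseline, and for signals that decompose into seven or fewer IMFs the
operation is then the identity, which is the safe default. Second,
min–max normalization statistics are computed per channel within each
recording (not corpus-wide), because the unit differences normalization
exists to remove are per-channel phenomena; it also pins padded zeros to
each channel's minimum.

## Sampling-rate selection

The rate is chosen from the data, not assumed. For every sample the 72
channel spectra (n-point FFT, n = smallest power of two covering the
longest padded segment, fixed per corpus; DC excluded) are summed per bin,
bins are grouped by the ceiling of their frequency in Hz, and the
accumulated amplitude up to each integer N = 1..50 Hz is normalized by the
≤50 Hz total. Percentages are averaged over samples, then tasks. The
cutoff is the smallest N beyond which every per-Hz gain stays below a
threshold (default 1%/Hz, configurable since a visual knee is being
formalized), and the selected rate is twice the cutoff (Nyquist). On
default synthetic corpora the knee lands at 10 Hz and the selected rate at
20 Hz; decimating 100 Hz data by the factor 5 removes 80% of samples.
Decimation keeps every f-th sample starting at index 0 and requires an
integer factor; no extra anti-alias filter is applied by default because
EMD denoising has already suppressed content near the old Nyquist
frequency (an optional Butterworth low-pass flag exists).

## Oversampling augmentation

Class balancing raises every class to N samples (defaults k = 2, N = 60)
by interpolating between a uniformly drawn class member x and one of its
k nearest same-class neighbours x_k (Euclidean distance over the flattened
time×channel matrix, ties to the lower index, neighbours always drawn
from original samples, x redrawn with replacement across rounds). The
default generation rule is deliberately the literal one,

    x_new = x + rand(0,1) · |x − x_k|,

whose element-wise absolute difference biases generated points upward from
x; the standard signed SMOTE direction x + rand·(x_k − x) is available as
`mode="smote"`. Both are kept, and labelled, because they are genuinely
different generators and silently "correcting" the former would change
the method. The blend coefficient is one scalar per generated sample by
default (`per_element` available). Under-sampling is refused. Every
generated sample's parentage and blend value is logged in a provenance
table.

Placement relative to cross-validation matters: the package defaults to
balancing *inside* each training fold (`leakage_mode="fold_internal"`), so
no generated sample straddles the train/test boundary; the alternative
`"pre_split"` mode balances the whole dataset before splitting, an
arrangement some studies use when evaluating on balanced data, but it lets
interpolated near-duplicates of test samples into training folds. Both are
exposed; reports state which was used.

## Classifier family

Seven variants are assembled from two heads and a shared meta-learner.
A conv head is Conv1D(64 filters, ReLU, same padding, stride 1) →
MaxPool(2) → Flatten; a GRU head is a 64-unit gated recurrent layer
emitting its state at every timestep, flattened ("time-distributed"), so
long sequences are not compressed into one fixed vector. Variants: C
(kernel 3), G, DC (kernels 1, 3), TC (1, 3, 5), C-G (conv + pool feeding
the GRU sequentially), C+G, and DC+G (kernels 1, 3 plus GRU). The
meta-learner is Dense(100, ReLU) → Dropout(0.5) → softmax(5). Heads and
meta-learner train jointly under one loss — the "stacking" here is
architectural, not out-of-fold stacking. The GRU consumes the 72-channel
input directly with hidden size 64 (no projection layer); in C-G the pool
layer is retained before the GRU, halving the recurrent sequence length.

The numerical core is written in numpy with hand-derived backpropagation,
including GRU backprop-through-time, verified against finite differences
to ~1e-7 relative error. Conventions: Glorot-uniform weight init (seeded),
zero biases, single-bias GRU (3·(in·units + units² + units) parameters),
pooled length floor(T/2), single-precision arithmetic. Closed-form shape
and parameter counts (e.g. the DC+G concatenated feature length
50·64 + 50·64 + 100·64 = 12,800 at T = 100) are asserted against the built
networks.

## Training and evaluation protocol

Adam (learning rate 0.001), categorical cross-entropy, per-task batch
sizes {64, 32, 64, 16, 32, 32, 32, 64, 32, 64, 64, 64, 64, 64} for tasks
1–14, early stopping with patience 20 and a cap of 500 epochs, restoring
the weights of the best monitored epoch. The monitored quantity defaults
to training loss (the protocol defines no validation split; a 10%
carve-out is available via `monitor="val_loss"`). An improvement must
exceed `min_delta` = 1e-3 nats to reset patience — with a zero threshold,
float jitter around a converged loss can postpone stopping indefinitely.
The "mean epoch" statistic counts epochs actually run (the stopping epoch,
not the best epoch). Evaluation is stratified 10-fold cross-validation;
accuracy is the only metric because evaluated datasets are class-balanced.
Per-task reports aggregate to a grand mean and a population standard
deviation across the 14 task means. One master seed fans out to the split,
per-fold weight-init, augmentation and shuffle streams.

## Problem sizes in the shipped tests

The test suite and acceptance script run the study at desk scale, chosen
once as the package's default conditions: spectral profiling uses three
tasks with six segments per class (90 segments, 72 channels — ample for a
profile that is averaged over samples and tasks); the class-recovery check
trains the full DC+G ensemble at 60 samples per class, 10 folds, full
stopping protocol, at separation 2.5 ("strongly separated"); the
chance-level check uses separation 0 with 20 samples per class and a
50-epoch cap, since training length cannot create class signal that is
absent by construction; the augmentation sweep compares N = 20 (i.e. the
20 originals per class, no synthesis) against N = 120 with the single-head
CNN variant and 5 folds. Larger corpora change none of the logic, only the
statistics' precision.

## Known limitations

* EMD boundary handling (mirrored extrema) can distort the outermost
  half-oscillation of an IMF; tests that compare IMFs against reference
  tones exclude the edges.
* The spectral profile uses rectangular-window FFTs of zero-extended
  segments, so tone leakage is part of the measured profile — as it would
  be in any fixed-length transform of real segments.
* The literal oversampling rule shifts class means upward by construction;
  that bias is the rule's defining property, not a bug, and `smote` mode
  is the remedy when it is unwanted.
* The numpy training loop is single-threaded; it is sized for hundreds of
  samples per task, not for large-scale corpora.
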