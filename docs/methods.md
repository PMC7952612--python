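# Methods

## Signal model of the simulator

A simulated recording is a linear superposition, per channel `c` and time
`t`:

```
x_c(t) = A_erp · p_c · g(t − t_k − δ_k)        for each target onset t_k
       + A_ssvep · q_c · sin(2π f_stim t)       while a block is running
       + pink_c(t) + white_c(t)                 [+ blink artifacts]
```

- `g` is a positive unimodal Gaussian pulse, peak latency 0.30 s, width
  (SD) 0.08 s. Its energy is concentrated below 4 Hz, so it lives in the
  Delta band like the P300-family responses it emulates. Peak latency and
  width are configurable.
- `δ_k` is per-trial latency jitter, Gaussian with SD 0.03 s by default,
  truncated at ±2 SD. Real single-trial responses vary in latency and
  duration; a truncated Gaussian is the simplest defensible choice.
- `p` and `q` are unit-norm spatial patterns over channels. In the
  cross-session benchmark they are drawn once per simulated *subject* and
  held fixed across that subject's sessions — topography is anatomy, not
  session state — while noise and jitter are redrawn every session.
- The steady-state response (`f_stim` = 10 Hz) is gated to block intervals
  and present regardless of stimulus class, as in real RSVP recordings.
- `pink` has a 1/f^α amplitude spectrum (α = 1 by default) and `white` is
  i.i.d. Gaussian; both scaled to a target SD.
- Blink artifacts are rank-1 positive bumps (SD 0.15 s) on a frontal
  spatial pattern at Poisson-distributed times; off by default.

Stimulus streams follow the experimental design exactly: blocks of 100
pictures at 10 Hz with no gaps, `round(block_size × fraction)` targets per
block (round-half-even), pictures sampled without replacement from a pool
partitioned into target/non-target id sets, 14 blocks per session at full
scale, a 2 s inter-block gap (the design does not state inter-block
timing; 2 s leaves room for full edge epochs). The per-block target count
with a 1400-picture pool at 4% reproduces the canonical 4-of-100 and
56/1344 pool split. An optional `min_target_gap` enforces a minimum
spacing between targets in a block; default 0 (random order may place
targets adjacently).

### What the simulator does not emulate

No head geometry or forward model, no sensor-type scaling, no
heteroscedastic or non-stationary noise, no eye movements other than the
stylised blink, no behavioural (button-press) stream, and the evoked
response is strictly rank-1 and class-deterministic. Passing the recovery
benchmark therefore demonstrates that the pipeline's machinery —
labeling geometry, overlap handling, filter estimation, training and
fold bookkeeping — is correct under known ground truth; it does not
certify performance on real recordings.

## Preprocessing

ICA is fitted (FastICA) on a 1 Hz high-passed copy — the decomposition is
sensitive to drift — and applied to the unfiltered data. Components are
rejected when the **robust** z-score (median/MAD across components) of
skewness, kurtosis or variance exceeds 3.0. Robust scaling matters: a
classical mean/SD z-score of `n` values is bounded by `(n−1)/√n`, which is
below 3 whenever `n ≤ 10`, so a single artifact component among few could
never be flagged. If every component would be marked the operation refuses
rather than zeroing the recording.

Downsampling is polyphase with anti-aliasing (1200 → 100 Hz at full
scale). The band-pass (0.1–15 Hz default) is zero-phase; the low edge is
implemented by *subtracting* a 4th-order low-pass at 0.1 Hz because a
direct high-pass design that close to DC (0.002 of Nyquist at 100 Hz)
carries visible numerical error, and its edge transients span tens of
seconds (noted for short test signals). Zero-phase filtering is essential
here: phase delay would shift response latencies and corrupt the ±0.5 s
labeling geometry.

Epochs are −0.2…+1.2 s around onsets (140 samples at 100 Hz); events whose
window leaves the recording are dropped with a warning, never zero-padded.
Baseline correction (mean of −200…0 ms) precedes the per-epoch linear
detrend; the order is configurable since the two operations do not
commute exactly.

## Labeling

Targets are always code 1, even when two targets are adjacent. A
non-target becomes near (3) when any target onset in the same session lies
within the window — **inclusive**, which matters on the 10 Hz grid where
distances hit 0.5 s exactly — and far (2) otherwise. The window is
symmetric by default: epochs extend 200 ms before onset, so a target on
either side leaks response energy into the epoch. One-sided modes
(`before_only`, `after_only`) are provided for ablation. Distances never
cross session boundaries. Under the symmetric inclusive rule an isolated
target on a 10 Hz grid converts exactly 10 neighbours (5 each side).

Balanced sampling draws `n_total / n_classes` epochs per class, without
replacement when the class is large enough, with replacement otherwise
(logged) — targets at 4% prevalence routinely need replacement.

## Evoked estimation and spatial filtering

With 100 ms between stimuli and ~1 s responses, neighbouring responses
overlap; the onset-locked average is biased. The evoked template is the
least-squares solution of `X ≈ (D Aᵀ)ᵀ` where `D` is the 0/1 Toeplitz
design stacking a shifted identity per target onset. On non-overlapping
designs this reduces exactly to the average; the normal equations are
solved per channel, with a trace-scaled ridge fallback if the design is
singular (logged).

Filters maximise the SSNR Rayleigh quotient of the pencil
`(Σ_signal, Σ_total)`, where `Σ_signal` is the covariance of the
reconstructed evoked time course and `Σ_total` that of the recording;
eigenvalues lie in [0, 1] and are reported as `ssnr_values`. When
`Σ_total`'s condition number exceeds 1e8 a scalar trace shrinkage is
applied (stepped up from 1e-6 until conditioning is acceptable, logged) —
relevant for 272-channel data, not the 16-channel benchmark. Both a
continuous-data and an epoched entry point are provided (which the
original analysis used is unstated); the default component count is 6 and
the template length equals the epoch length (140 samples).

Fitting always uses training folds only; models are frozen before
transforming test data.

## Classifiers

**SVM.** RBF kernel, `gamma="scale"`, `class_weight="balanced"`
(`w_k ∝ 1/n_k`, so `w_k n_k` is constant across classes), one-against-one
for the ternary case, `C = 1.0` (unstated in the source configuration;
exposed). Input is the flattened 6 × 140 xdawn feature block (840-dim).
The target "probability" is a documented surrogate — pairwise margins
through a logistic, averaged over machines involving the target class —
used only where a score is needed; ROC analysis uses the CNN softmax.

**Compact CNN.** The DeepConvNet/EEGNet family, implemented in numpy
(forward, backprop, Adam) because no deep-learning framework is a
dependency of this package:

1. temporal convolution (valid, per channel) — kernel 11, 8 filters at
   desk scale;
2. spatial convolution collapsing the channel axis — 16 filters;
3. ELU, max-pool 3; then conv-pool blocks (kernel 5, 32 filters, one
   block at desk scale);
4. dense layer to a k-way softmax.

Initialisation is seeded uniform fan-in. Inputs are standardised per
channel with training-set statistics stored in the model. Training runs
`n_epochs` epochs; each draws a class-balanced sample (batch 90 desk / 300
full) and takes Adam steps on minibatches of 30 with cross-entropy against
one-hot labels. The learning rate is exactly
`0.001 × 0.8^⌊epoch/50⌋`. Single-threaded runs are bit-deterministic for a
fixed seed. The full-scale preset (272 channels, 25 temporal/spatial
filters, blocks of 50 and 100, 500 epochs) mirrors the published
deployment; exact layer sizes of the original network were never printed,
so the family is configurable and nothing downstream depends on parameter
counts. The source description conflates two published architecture names;
we implement one configurable family covering the deeper variant.

## Evaluation

Leave-one-session-out: each session is the test set once; 11 folds at full
scale. Ternary predictions are merged (1 → target, {2,3} → non-target)
before scoring, so all four method variants are scored on the identical
binary task; recall/precision/F1 use target as the positive class, with a
0-with-warning convention for empty denominators. Accuracy is computed
over all epochs — with 96% non-targets it sits far above recall whenever
the true-negative rate is high, which is why accuracies cluster near 0.99
while recall is ~0.85 at full scale.

The confusion matrix is 3×3 in (target, near, far) order with
row-normalised percentages; a row with no true members is NaN, not 0.
AUC is trapezoidal over the ROC of the CNN's softmax target probability.
The three-factor ANOVA is the classical balanced main-effects
decomposition (marginal-mean sums of squares; F against the residual mean
square); it refuses unbalanced designs, and degrees of freedom are always
computed from the data at hand. Paired t-tests compare methods on
per-subject-per-fold scores. t-SNE projections are for reports only and
never feed scoring.

## The desk-scale recovery benchmark

2 subjects × 3 sessions × 4 blocks of 100 stimuli, 16 channels, evoked
amplitude 10 against unit-total noise, latency jitter SD 0.01 s. The
regime is deliberately easy: the single-trial response is unambiguous and
jitter is small against the 100 ms stimulus spacing, so recovery failures
indicate implementation defects, not irreducible class overlap. (At
realistic jitter — SD 0.02 s and above — a late-jittered target is
genuinely confusable with the non-target flashed 100 ms before the target,
and ternary-SVM F1 saturates near 0.89 regardless of amplitude; that
regime is available through the configuration but is not the recovery
check.) A full run takes about 3 minutes on one CPU; problem sizes
throughout the test suite are chosen to keep the whole suite in the
minutes range.

## Known limitations

- The numpy CNN is CPU-only and modest in scale; the full 272-channel
  preset trains slowly compared to a GPU framework.
- The SVM score surrogate is not a calibrated probability.
- The ANOVA is main-effects only (matching the reported analysis); no
  interactions, no multiple-testing correction.
- The simulator's rank-1, class-deterministic evoked model understates the
  variability of real recordings; see the simulator section for the full
  list of omissions.
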