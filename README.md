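# rsvperp

Single-trial detection of target-evoked brain responses in rapid serial
visual presentation (RSVP) experiments, using **ternary labeling** of
overlapping epochs.

## The problem

In an RSVP brain–computer interface, pictures flash at 10 Hz with no gaps
and a small fraction (4%) are targets. Targets evoke a P300-like response
peaking near 300 ms — but each analysis epoch spans −200…+1200 ms, so an
epoch around a *non-target* flashed within half a second of a target still
contains the target's evoked response, merely at the wrong latency. A
binary classifier (target vs. non-target) is forced to call these
"near-non-targets" noise, which costs precision.

The ternary trick: train with three labels —

| code | class | epoch content |
|------|-------|----------------|
| 1 | target | evoked response at the correct latency |
| 3 | near-non-target | evoked response at the wrong latency (a target onset within ±0.5 s) |
| 2 | far-non-target | no evoked response |

— then **merge** codes 2 and 3 back to "non-target" when scoring. The task
stays binary; only the training signal changes. The classifier learns
"response present?" and "latency correct?" as separate questions.

## What the package provides

- `rsvperp.simulate` — RSVP stimulus streams (blocks/sessions, exact 10 Hz
  spacing, 4% targets sampled without replacement from a picture pool) and
  MEG-like recordings: a Delta-band evoked response on targets only
  (Gaussian pulse, peak 0.30 s, jittered latency), a steady-state visual
  response at the presentation rate in all classes, 1/f plus white sensor
  noise, optional blink artifacts. Fully seeded.
- `rsvperp.preprocess` — ICA artifact suppression (robust z-scores of
  component skewness/kurtosis/variance), polyphase downsampling to 100 Hz,
  zero-phase 0.1–15 Hz band-pass, −200…+1200 ms epoch extraction (140
  samples at 100 Hz), baseline correction and linear detrend.
- `rsvperp.labeling` — the ternary rule (±0.5 s window, inclusive,
  symmetric by default), merge-to-binary, and class-balanced sampling.
- `rsvperp.xdawn` — overlap-aware evoked estimation by least squares on a
  Toeplitz stimulus design, and spatial filters maximizing the
  signal-to-signal-plus-noise ratio (SSNR), the generalized eigenproblem
  `Σ_s w = λ Σ_x w` with SSNR = `wᵀΣ_s w / wᵀΣ_x w ∈ [0, 1]`; 6 components
  by default.
- `rsvperp.classifiers` — an RBF SVM (gamma = "scale", balanced class
  weights, one-against-one) on flattened xdawn features, and a compact CNN
  (temporal convolution → spatial convolution → conv-pool blocks → softmax)
  written in numpy with its own backprop and Adam, trained on
  class-balanced batches with the step-decay schedule
  `lr(e) = 0.001 × 0.8^⌊e/50⌋`.
- `rsvperp.evaluate` — leave-one-session-out cross-validation,
  merged-binary recall/precision/F1/accuracy, 3×3 confusion matrices,
  ROC/AUC from the CNN softmax, a balanced three-factor
  (subject × method × fold) ANOVA, paired t-tests, band-averaged class
  waveforms and t-SNE feature projections.

## Worked example

```python
from rsvperp.evaluate import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(seed=1))
print(report.summary.round(3))
```

prints (2 simulated subjects × 3 sessions, 16 channels, ~3 minutes on one
CPU):

```
            recall precision     f1 accuracy
              mean      mean   mean     mean
method
cnn_binary   0.927     0.977  0.951    0.996
cnn_ternary  0.979     1.000  0.989    0.999
svm_binary   0.906     1.000  0.949    0.996
svm_ternary  0.917     0.989  0.951    0.996
```

Rows are the four method variants (SVM / compact CNN, trained binary /
ternary); all scores are computed on merged binary labels of the held-out
session, with "target" the positive class. In this easy high-SNR regime
every method detects well, and the ternary CNN's precision matches or
beats the binary CNN's — the qualitative signature of the ternary method.

A command-line interface covers each stage (`rsvperp simulate`,
`preprocess`, `label`, `xdawn`, `train`, `evaluate`, `run-all`); see
`rsvperp --help`.

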