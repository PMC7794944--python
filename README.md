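# pupglearn

Hypertension screening from pulse-plethysmograph (PuPG) signals.

A PuPG sensor is a piezoelectric finger probe that senses pressure changes
in the blood flow (unlike optical PPG, which measures transmitted light).
Sustained high blood pressure changes the pulse waveform — a damped
dicrotic wave, broader spectral content, higher kurtosis — and those
changes are learnable from 10 s single-channel recordings.  `pupglearn`
implements a complete two-class (normal vs. hypertension) classification
pipeline for such recordings, plus a seeded synthetic generator so the
whole pipeline runs and is testable without any clinical data.

## The method

For a raw record x(t) (10 s at 1 kHz by default), four stages:

1. **Denoising** — one of two routes:
   * *EMD route*: sift x into intrinsic mode functions IMF₁…IMF_K plus a
     residual trend.  IMF₁ carries the highest-frequency content (50 Hz
     powerline pickup, circuit noise) at ~0–1 % relative energy, and is
     dropped; the signal is rebuilt from IMF₂…IMF_K + residual.  A
     generalized rule drops any IMF with relative energy below and
     spectral centroid above configurable thresholds.
   * *DWT route*: L-level Symlet-8 decomposition; detail bands D1–D4
     (≈31–500 Hz at 1 kHz) are zeroed before reconstruction, keeping the
     ≈99 % of pulse energy that lives below ~31 Hz.
2. **Features** — a fixed registry of 102 features per record in nine
   families: 19 time-domain statistics, 17 spectral descriptors (centroid,
   roll-off, flatness, SFDR, SINAD, THD, …), 4 MFCC + 4 GFCC cepstral
   coefficients, a 12-bin chroma profile, 13 sEMG-style waveform
   descriptors, 6 root-squared-moment descriptors, Hjorth mobility and
   complexity, 5 fractal/chaos measures (Higuchi and Katz dimensions,
   largest Lyapunov exponent, approximate entropy, correlation dimension),
   and a 20-bin local-ternary-pattern texture histogram.
3. **HFSR** (hybrid feature selection and reduction) — seven rankers
   (Welch t, symmetric KL, Bhattacharyya, |AUC−½|, Mann–Whitney |z|,
   mRMR, ReliefF) each produce integer ranks 1…F (best = F); the
   per-feature **mean rank** MR = (1/7)Σ ranks fuses them, the top 24
   features by MR are kept, and kernel PCA (RBF, γ = 1/d) reduces them to
   a handful of components (5 by default).
4. **Classification** — weighted k-NN (k = 10, 1/d² votes) plus a roster
   of 18 standard baselines, evaluated by stratified 10-fold
   cross-validation with the ranking, selection and KPCA refitted inside
   every training fold.  Reports pool the per-fold confusion matrices;
   hypertension is the positive class.

## Worked example

```
$ pupglearn synth --n-per-class 10 --seed 7 --out demo/
wrote 20 signals to demo (manifest.csv)

$ pupglearn run-all --manifest demo/manifest.csv --method emd --folds 5 --seed 7 --out runs/
{"tp": 10, "fn": 0, "fp": 0, "tn": 10}
method=emd acc=1.0000 sen=1.0000 sp=1.0000 err=0.0000 (artifacts: runs/emd-ea797039dfff)
```

The confusion matrix counts pooled test-fold predictions: all 10
hypertensive and all 10 normal synthetic records are classified correctly,
so accuracy, sensitivity (hypertension recall) and specificity (normal
recall) are all 1.0 and the error rate is 0.  The run directory holds the
102-column feature matrix, the seven-method rank table with its MR column,
the 24 selected features, the report JSON and a log of every effective
parameter.

The same stages are available as library calls
(`generate_signal`, `emd_denoise`, `extract_all`, `rank_table`,
`kpca_fit`, `cross_validate`, …) and as individual subcommands
(`preprocess`, `features`, `rank`, `reduce`, `evaluate`, `compare`,
`sweep`).

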