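# Methods

## Signal model and the synthetic benchmark

Real PuPG records are quasi-periodic pressure pulses: a systolic peak, a
delayed dicrotic wave, slow baseline wander, 50 Hz powerline pickup and
wideband circuit noise.  The generator models each beat as two Gaussian
bumps,

    beat(t) = A_s exp(-(t-t_s)^2 / 2w_s^2) + A_d exp(-(t-t_s-d)^2 / 2w_d^2),

with beat onsets produced by a jittered instantaneous heart rate, plus a
sinusoidal wander term, a 50 Hz tone and low-pass-filtered Gaussian noise.
Defaults (all configurable through `SynthConfig` / `ClassMorphology`):

| parameter | normal | hypertension | unit |
|---|---|---|---|
| heart rate (mean / per-beat SD) | 72 / 3 | 78 / 3 | bpm |
| systolic amplitude / width | 1.0 / 0.06 | 1.0 / 0.06 | a.u. / s |
| dicrotic amplitude / delay / width | 0.35 / 0.30 / 0.08 | 0.175 / 0.22 / 0.08 | a.u. / s / s |
| noise SD / bandwidth | 0.02 / 100 | 0.02 / 130 | a.u. / Hz |
| powerline amplitude (50 Hz) | 0.02 | 0.02 | a.u. |
| wander amplitude / frequency | 0.10 / 0.25 | 0.10 / 0.25 | a.u. / Hz |

The class contrast — dicrotic wave halved and earlier, noise band +30 % —
qualitatively reproduces the reported differences between classes (higher
spectral roll-off/flatness and kurtosis under hypertension).  No
quantitative morphology estimates exist for either class, so these values
were fixed once as physiologically plausible; `SynthConfig.with_contrast`
scales the contrast for separability studies.  Records are 10 s at
1 kHz; every record draws from an RNG stream keyed by (seed, class,
index), so datasets are bit-reproducible and order-independent.

**What the benchmark does not emulate:** inter-subject morphology
variability beyond beat-time jitter, motion artifacts, sensor coupling
drift, arrhythmias, or any physiological hemodynamics.  The synthetic
classes are much cleaner than clinical data, so a near-perfect
cross-validated score on the benchmark demonstrates that the pipeline is
correctly wired and leakage-free — not that comparable accuracy would be
reached on real recordings.

## Denoising

*EMD.*  Sifting uses cubic-spline envelopes through the local extrema,
with the first/last two extrema mirrored about the record ends (standard
boundary handling).  One mode is accepted when the Cauchy criterion
SD = Σ(h_prev−h)²/Σh_prev² drops below 0.2 or after 10 sifting passes;
extraction stops when the residual has fewer than 3 extrema or after 10
modes.  These are the canonical sifting defaults; the stopping numbers are
exposed as parameters.  The decomposition is additive by construction, so
keep-everything reconstruction is exact to float precision.  The default
rejection rule drops IMF1 only; the generalized rule drops modes with
relative energy below and spectral centroid above given thresholds.  The
"mean frequency" of a component is its power-spectrum centroid — a
deterministic, testable operationalization of a component's frequency
range.

*DWT.*  `pywt.wavedec` with Symlet-8 and periodization mode (exactly
invertible at any depth).  Detail level l nominally occupies
[fs/2^(l+1), fs/2^l]; with fs = 1 kHz the default drop set {D1..D4}
removes ≈31–500 Hz.  The wavelet order is configurable; sym8 is the
common choice for plethysmographic morphology.  Subband energies are
coefficient energies normalized to 100 % (Parseval holds for orthogonal
wavelets).  Note the analysis filters are not brick-wall: a tone near a
band edge leaks ~10 % of its energy into the neighbouring band.

## Feature registry

The 102 features follow the standard definitions of their families; the
constants below are defaults, chosen once for 10 s / 1 kHz records:

* spectral roll-off at 95 % of energy; spectral flux over 1 s frames with
  0.5 s hop (unit-normalized frame spectra); THD over 5 harmonics with the
  largest nonzero-frequency peak as fundamental; SFDR/SINAD with a ±2-bin
  guard around the fundamental;
* framing for MFCC/GFCC/chroma: 1024 samples, hop 512, Hann window,
  20 mel filters (0–fs/2) with log compression, 20 ERB-spaced gammatone
  channels (10 Hz–fs/2, 4th-order spectral magnitude weights) with
  cubic-root compression; orthonormal DCT-II, coefficients 1–4,
  averaged over frames; chroma accumulates bin magnitudes into 12 pitch
  classes referenced to A440 and is left unnormalized;
* sEMG thresholds (slope-sign-change, Willison amplitude, myopulse rate)
  default to 0.01 signal units; the enhanced variants use exponent 0.75
  inside the central 60 % window and 0.5 outside;
* Higuchi dimension with kmax = 10; ApEn with m = 2, r = 0.2·SD;
  Rosenstein Lyapunov and Grassberger–Procaccia correlation dimension with
  embedding dimension 5 and delay at the first autocorrelation zero
  crossing; the Lyapunov divergence is fitted over 1 s and reported per
  second;
* the 1-D local ternary pattern compares 8 neighbours (4 per side)
  against a ±0.01 dead zone and bins the upper/lower binary halves into
  rotation-invariant uniform histograms (9 uniform classes + 1
  non-uniform), kept as raw counts.

Numerical choices: the pairwise-distance-based chaos features (Lyapunov,
ApEn, correlation dimension) run on a 10×-decimated copy of the record
(100 Hz, 1000 samples for the default records) because their O(N²) pair
counts are impractical at N = 10⁴; the decimation factor is a parameter.
Spectral centroid/spread use magnitude weights while mean/median
frequency use power weights — this keeps the two descriptor pairs
distinct, as they are in practice.  Any feature that is undefined on a
degenerate input (zero variance, vanishing derivatives) is replaced by a
0.0 sentinel with a warning; `extract_all` always returns a finite
102-vector.  No feature consumes randomness.

## Rank fusion and reduction

Scores are converted to integer ranks 1..F (best = F) with mid-rank ties
rounded half-up, preserving rank-sum conservation (mean MR = (F+1)/2
without ties).  Estimator choices the rankers leave open were fixed as:
Gaussian closed forms for the symmetric KL and Bhattacharyya distances;
mutual information on 10 equal-frequency bins with greedy
MID (relevance − mean redundancy) ordering for mRMR, scored by selection
order; ReliefF with k = 10 neighbours over all samples on
range-normalized features.  The selection threshold is operationalized as
top-k with k = 24 (the published final selection size); an explicit MR
cutoff is equivalent for a fixed dataset.  KPCA defaults to the RBF
kernel with γ = 1/(d·mean feature variance) — i.e. 1/d after the
training-fold z-scoring — with linear and polynomial kernels available
for sensitivity checks; component counts are taken in eigenvalue order
(presets S1–S6 = 5, 7, 10, 12, 15, 17 components).

## Classification and evaluation

KNN-W stores the z-scored training set and votes with weights 1/d²;
zero-distance neighbours dominate (a query on a training point takes its
class), and exact vote ties fall back to the single nearest neighbour.
The baseline roster wraps standard scikit-learn estimators (SVMs, KNN
variants, trees, discriminants, naive Bayes, boosted/bagged/subspace
ensembles) behind one name-resolving factory; the kernel naive Bayes
uses per-feature Gaussian KDE class-conditionals.

Cross-validation is stratified and shuffled with the run seed.  All
selection statistics (ranking, top-k, KPCA, classifier) are fitted inside
each training fold; the pooled confusion matrix keeps integer counts.
Holdout fractions 0.20/0.25 are supported.  The label-permutation control
repeats the full in-fold pipeline on permuted labels and should land at
chance (0.5 on the balanced benchmark) — the suite asserts this, which is
the practical guard against selection leakage.

## Problem sizes used in the checks

The packaged benchmark runs 100 records per class (10 s at 1 kHz), 10-fold
CV, and 5 label permutations; oracle-equivalence checks use 50 fuzz
signals of 512 samples and toy sets of ≤ 20 points.  These sizes make the
whole verification run in a few minutes on one CPU while keeping every
stage's statistics meaningful.

## Known limitations

* The synthetic benchmark is far easier than clinical data (see above);
  reported benchmark scores are upper bounds of wiring correctness only.
* EMD mode mixing is not mitigated (no ensemble EMD); heavily
  noise-dominated records can smear components across modes.
* The Lyapunov exponent's scale depends on the decimation and embedding
  choices; it is a comparative feature here, not a validated dynamical
  invariant.
* The mRMR and ReliefF estimator variants are reasonable fixed choices;
  other variants would permute near-tied mid-table ranks (the fusion is
  designed to be robust to exactly this).
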