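# Methods

`mammoseq` implements a temporal analysis of *antecedent* screening
mammograms: given a woman's sequence of craniocaudal (CC) exams acquired
before any abnormality was detected, predict whether the abnormality that
eventually prompted a biopsy will prove malignant or benign.  The working
hypothesis is a **field effect**: tissue changes associated with a future
cancer extend beyond the eventual lesion — including into the contralateral
breast — so the *temporal evolution* of parenchymal texture carries signal
that no single exam does.

## Pipeline

1. **ROI** — a 512 × 512-pixel square placed in the central breast region
   posterior to the nipple (native 70 µm pixels; no resampling).  Manual
   centers from the manifest always override the automated Otsu-centroid
   heuristic.
2. **Features per ROI** — either the 50-feature radiomic bank or pooled CNN
   descriptors (below).
3. **Sequence classifier** — an LSTM over the chronologically ordered
   per-exam feature vectors of one breast.
4. **Single-timepoint baseline** — PCA to 25 components + SVM on the last
   antecedent exam only.
5. **Evaluation** — shared, stratified, case-grouped 5-fold cross-validation;
   ROC/AUC with DeLong inference; paired DeLong tests for the pre-registered
   comparisons; Holm–Bonferroni correction; classifier merging by per-case
   score averaging (merged classifiers are reported without tests).

## The radiomic bank (50 features)

Eight families in a frozen registry order: box-counting fractal dimension
(6), Sobel edge gradient (4), first-order histogram (10), Fourier spectrum
(2), NGTDM (5), Minkowski/blanket fractal dimension (1), spectral power-law
β (8), and GLCM/Haralick (14).  The family sizes are fixed; the individual
definitions inside each family are this package's documented selections
(`radiomics.FEATURE_REGISTRY`), since texture workstations differ in these
details.  Numerical conventions: logarithms base 2 with 0·log 0 ≡ 0,
ε = 1e−12 denominator guards, GLCM at 16 gray levels / distance 1 / four
angles averaged / symmetric, min–max gray-level quantization on the ROI's
own range (making all co-occurrence, NGTDM and entropy features exactly
invariant to additive intensity offsets).  Spectral fits exclude annuli
closer than 3 frequency samples to DC; power-law slopes are computed for
{Hann, no window} × {full band, low/mid/high log-frequency third}.  Sum
variance is taken about the sum average; the maximal correlation coefficient
is √(second-largest eigenvalue of Q), defined as 0 for degenerate matrices.

**Known limitation — fractal estimators.**  Differential box counting (boxes
2…128) and the blanket method (ε = 1…8) are implemented in their classical
forms.  On lattice fBm phantoms both carry the well-documented negative bias
of max-statistic estimators: the expected range over an s × s block is
s^H·g(s) with g(s) increasing toward the continuous supremum, so the
log–log slope over-estimates H, the more so the rougher the surface.
Measured on careful phantoms (8× supersampled spectral synthesis, decimated;
structure-function local Hurst exponents within 0.03 of nominal), the
estimators track 3 − H monotonically and agree with it to ≈0.1–0.2 only for
smooth surfaces (H ≳ 0.7); at H = 0.3 the deficit is ≈0.3.  They remain
useful *ordinal* texture descriptors, which is how the classifier uses them.
The power-law β estimator, in contrast, recovers the generator slope to
≈0.01 across β ∈ [1.5, 2.8].

## Pooled CNN features

Backbone-agnostic multi-stage transfer learning: run a VGG-style stack, take
the output of each max-pooling stage, global-average-pool it over space (one
value per channel), concatenate.  The VGG-19 layout has stage widths
(64, 128, 256, 512, 512) → 1472 features.  The forward pass is pure NumPy
(3 × 3 same-convolutions via im2col, ReLU, 2 × 2 max pooling).  ROIs are
min–max scaled to [0, 1], replicated to three channels, and by default run
fully convolutionally at native size (a 224 × 224 resize is available).
Weights are seeded He-normal random draws by default — the random-projection
flavour of pooled-feature transfer learning, and what all tests use — or an
optional `.npz` of pretrained kernels; nothing in the package downloads
anything.  A two-stage `tiny-test` backbone (8, 16 channels) keeps tests
fast.

## The LSTM

Standard single-layer gated recurrence (sigmoid input/output/forget gates,
tanh candidate and cell activation) with a per-step sigmoid read-out; the
per-case risk score is the read-out at the last valid step.  Sequences are
zero-padded at the tail to the batch maximum, with a validity mask; the
binary cross-entropy loss is accumulated over valid steps only and divided
by the number of valid steps (a per-sequence averaging variant is a config
flag).  Predictions and loss are therefore *exactly* invariant to extra
padding.  Training is plain minibatch SGD (no momentum, no decay, no early
stopping), with full BPTT gradients that match central finite differences to
1e−5 relative.  Features are z-scored per feature with statistics from
training-fold valid steps only; padded cells are re-zeroed after scaling.

Hyperparameter defaults in `LSTMConfig` are the method's published operating
point (hidden 512, lr 1e−4, 100 epochs, batch 8), selected on real
1472-dimensional data.  For the synthetic feature-level cohorts used in this
package's experiments that point leaves the network essentially untrained at
n ≈ 160, so the experiment configs use a smaller, faster operating point
found by the same kind of limited sweep: hidden 8, lr 0.5, 300 epochs.  Both
are explicit config values; nothing is hidden in code.

## Single-timepoint baseline

Features of the chronologically last antecedent exam are z-scored (the 50
radiomic features span wildly different scales), reduced by PCA to 25
components (deterministic sign convention: each component's
largest-magnitude loading is positive), and classified by an RBF SVM
(C = 1).  The continuous decision margin feeds the ROC directly — AUC is
rank-based, so calibration is unnecessary.  Scaler, PCA and SVM are fit
strictly inside each training fold.

## Evaluation statistics

AUC is the Mann–Whitney statistic with ties counted ½.  Standard errors,
confidence intervals, tests against chance (z = (AUC − 0.5)/SE, two-sided)
and paired comparisons use DeLong's placement-value method; the paired
variance is covariance-aware, so classifiers evaluated on the same folds are
compared efficiently.  (The original analysis used proprietary binormal ROC
software for these comparisons; DeLong is the standard nonparametric
substitute and is what this package documents and reports.)  Holm–Bonferroni
controls the family-wise error over the pre-registered comparisons.  Fold
assignment is case-level, stratified by label (round-robin after a seeded
within-class shuffle), and shared by every classifier so comparisons are
paired; all images/exams of a case stay in one fold.

## Synthetic cohort generator

No public accession exists for the original cohort, so the generator *is*
the study-conditions definition.  Structure: 99 cases by default (exact-count
allocation: round(prevalence·n) malignant, matching the 49/50 split), 2–9
exams per case with the probability mass at 2–4
(0.30/0.25/0.17/0.10/0.07/0.05/0.03/0.03 over lengths 2…9), inter-exam gaps
truncated-normal (mean 1.27 y, sd 0.3 y, floor 0.5 y), two breasts per exam,
random affected laterality.

**Image path.**  Parenchyma surrogates are power-law noise fields
(radially averaged spectrum ∝ f^(−β), β ≈ 2.8 baseline) plus Poisson-placed
Gaussian lumps — a clustered-lumpy-background-style texture whose parameters
the radiomic bank can recover — rescaled to the 12-bit range.  In
future-malignant cases β and lump density drift linearly with elapsed time
(scales: dβ/dyear = 0.05·δ, d log density/dyear = 0.1·δ), in the affected
breast and, when `field_effect` is set, equally in the contralateral breast.
Per-case baseline jitter of β (sd 0.05·`baseline_jitter`) keeps
single-timepoint marginals overlapping.

**Feature path** (fast, used by the classifier experiments).  Feature *j* of
one breast at elapsed time *t* is

    x_j(t) = J·s·w_j + e_j + [G v_t]_j + δ·t·w_j·(drifting)

with w_j ~ U(0.5, 1.5) fixed per cohort (per-feature sensitivity),
s ~ N(0,1) the breast's shared parenchymal-pattern factor (J = 9 by
default), e_j ~ N(0, 0.25²) small per-feature offsets, and v_t a rank-3
AR(1) visit-noise process (sd 0.1, ρ = 0.9).  δ = 0.5/year by default.  Two
properties are deliberate:

* the drift direction coincides with the shared factor's loading pattern, so
  every linear single-timepoint read-out is masked — the best achievable
  single-exam AUC is ≈ Φ(δ·E[T]/(√2·J)) ≈ 0.55, statistically
  indistinguishable from chance at n ≈ 160 — while the within-case change is
  large relative to visit noise (slope statistics reach AUC ≈ 1);
* between-case variation is dominated by the shared factor plus a low-rank
  noise process, emulating the strong inter-feature correlation of real
  texture banks.  This matters for learnability: with independent
  per-feature jitter, z-scoring inflates every noise dimension to unit
  scale and a small-sample LSTM memorizes instead of generalizing.

What the feature path does **not** emulate: nonlinear feature interactions,
scanner/institution shifts, ROI-placement variability, and any real
relationship between the 50 radiomic definitions and tissue biology.
Passing the classifier experiments therefore shows that the *pipeline*
recovers a temporal signal under the hypothesized field-effect structure —
not that real mammograms carry that signal.

The cohort *structure* depends only on `seed`; feature content additionally
depends on `feature_seed`, so several feature banks (the "cnn" and
"radiomics" stand-ins in the pipeline) can be generated over one identical
cohort, keeping folds and pairings aligned.

## Problem sizes used by tests and experiments

Classifier experiments run the feature-level path with n = 160 cases,
feature dimension 50, 5-fold CV, hidden 8 / lr 0.5 / 300 epochs; null
calibration uses 5 generator seeds at δ = 0; the headline-pattern check uses
3 seeds × both lateralities.  Spectral recovery uses 20 phantoms per β at
512²; fractal phantoms are 512² fBm surfaces synthesized 8× supersampled.
The full-size image path (318 exams × 2 breasts at 512²) runs in minutes and
is exercised end-to-end in miniature (64² ROIs, tiny backbone) by the test
suite.

## Reproducibility

Every stochastic component takes an explicit integer seed (generator,
weight init, batch shuffling, fold assignment); identical configs give
bit-identical cohorts, parameter trajectories, scores and reports.  The
pipeline writes its config and a content hash alongside every report.
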