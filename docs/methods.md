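# Methods

## Overview

`fnconn` implements an ICA-based functional network connectivity (FNC)
analysis for two-group resting-state fMRI studies, together with a
synthetic cohort generator that makes the whole chain testable by
parameter recovery. The pipeline is: group spatial ICA with PCA
back-reconstruction → selection of non-artifactual network components →
maximum lagged correlation between every pair of network time-courses →
group t-statistics with FDR control → supervised classification of
patients vs controls on the FNC feature vector, with strict train/test
separation.

## Synthetic cohorts

Each subject's data matrix (timepoints × voxels) is a linear mixture
`X = U S + ε`, where `S` holds K spatially compact network maps
(anisotropic Gaussian blobs on a jittered lattice; pairwise spatial
correlation is kept below 0.3 so the spatial ICA problem is
identifiable), `U` holds band-limited network time-courses, and `ε` is
i.i.d. Gaussian voxel noise.

Time-courses are realized with *exact* target covariance: white Gaussian
innovations are restricted to 0.02–0.12 Hz (comfortably inside the
0.017–0.15 Hz analysis band, so the analysis filter does not interact
with recovery tests), the empirical covariance of the realization is
whitened exactly, and the target correlation matrix's symmetric square
root is applied. The zero-lag correlation of the generated time-courses
therefore equals the target to machine precision; only the *lagged*
statistics carry sampling variability. Pair lags are realized by
spectral (FFT phase) delays of whole components; a set of pair lags must
be representable as per-component delays (`lag(i,j) = d_j − d_i`) and is
validated. Circular wrap-around from the FFT delay is negligible for
lags of a few seconds against 5-minute records.

Group differences are injected by `make_group_effect`, which shifts the
patient group's target correlations by a configurable delta on named
pairs (validated to stay inside (−1, 1) and positive semidefinite).

Defaults are fixed once at study scale: 28 subjects per group,
200 timepoints at TR = 1.5 s (a 5-minute run), a 12×12×8 desk-scale
grid, 9 networks, voxel noise SD 0.5 (noise comparable to the signal at
a blob's peak), subject-variability SD 0.1. Defaults the generator
does not take from the study design (effect sizes, motion coupling) are
explicit configuration, not claims about any real cohort.

The motion confound draws a per-subject motion amplitude from a
lognormal distribution, builds six smoothed random-walk rigid-body
parameters at that amplitude, and adds an amplitude-scaled band-limited
motion signal to every network time-course. Subjects who move more thus
have genuinely inflated FNC, and the per-subject motion summary (mean
absolute first difference of each parameter) is informative for the
nuisance regression that removes it.

What the generator does **not** emulate: scanner physics, physiological
noise spectra, spatial normalization artifacts, hemodynamic response
variability, non-stationarity. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to everything real data contain.

## Group spatial ICA

* **Two-level PCA.** Subject data are time-demeaned per voxel and
  reduced by temporal PCA to d1 dimensions (default 80, clamped to
  T−1); the reduced matrices are concatenated across subjects and
  reduced again to the model order K, with whitening.
* **Model order.** When K is not supplied it is estimated by the
  minimum description length criterion on the eigenvalue spectrum of the
  concatenated reduced data: the Gaussian log-likelihood of an isotropic
  noise floor (N·(p−k)·log of the arithmetic/geometric mean ratio of the
  trailing eigenvalues) plus the parameter-count penalty
  ½·k·(2p−k+1)·ln N. The i.i.d.-sample form is used; no correction for
  sample dependence.
* **Infomax.** Natural-gradient Infomax with the logistic nonlinearity
  on whitened data. Initial learning rate 0.1, annealed by ×0.9
  whenever successive gradient directions differ by more than 60°;
  tolerance 1e-6 on the relative weight change, at most 500 iterations
  (non-convergence returns the best iterate, flagged). The rate was
  chosen so that the standard 3-source Laplacian benchmark converges
  within the iteration cap (at 0.01 it does not). Components are
  sign-fixed so each source's largest-magnitude value is positive.
* **Stability.** ICA is repeated from `n_runs` seeded starts (default
  10); pooled components are clustered by average-linkage agglomeration
  on 1 − |spatial correlation| cut at K clusters. Cluster quality is
  mean intra-cluster minus mean extra-cluster similarity; the final
  component is each cluster's centrotype (the member with maximal summed
  intra-cluster similarity). A single run degenerates to quality 1.0
  with a warning. Final components are ordered by quality.
* **Back-reconstruction.** Subject maps and time-courses are recovered
  by PCA compression and projection: with the subject's de-reduction
  basis `F_s`, the group de-reduction block `G_s` and the ICA mixing
  matrix `A`, subject time-courses are `F_s G_s A` and subject maps are
  `(G_s A)⁺ R_s`, z-scored over the mask. A scan unseen at fit time is
  projected through a freshly computed reducer and the mean group block.

## Component selection and matching

Visual inspection is replaced by template matching: each named template
map claims a component, solved as a global optimal one-to-one assignment
on the absolute spatial correlation matrix (a greedy rule can cascade
mistakes). Assignments below a threshold (default |r| = 0.4) are left
unselected. Independent decompositions (training vs test ICA) are
matched the same way; the signed correlation of each matched pair is
kept so the test component's orientation can be aligned with training
before correlations are computed — without this, a sign-flipped
component would flip the sign of every FNC feature it participates in.
Synthetic runs use the generator's ground-truth maps as templates; real
runs take user-supplied template volumes.

## FNC features

Component time-courses are bandpass filtered (Butterworth order 5,
0.017–0.15 Hz, applied forward–backward so the filter itself introduces
no lag), then cubic-spline interpolated to a TR/10 grid (0.15 s at
TR = 1.5 s) so that sub-TR delays are detectable. For each component
pair the Pearson correlation of the overlapping segments is evaluated on
a lag grid covering −3…+3 s; the feature is the Fisher z (arctanh) of
the maximum signed correlation, and the lag at the maximum is recorded
but deliberately not analyzed further. Conventions:

* overlapping segments are mean-centered (Pearson by definition); the
  uncentered cosine form is available behind `mean_center=False`;
* positive lag means the second series lags the first;
* ties across lags break toward the smallest |lag|, then the negative
  lag;
* a near-constant segment (variance < 1e-12) yields correlation 0 with
  a warning; |r| = 1 is clipped to 1 − 1e-7 before arctanh;
* filtering precedes interpolation (filtering on the native grid avoids
  amplifying interpolation error).

Nuisance covariates (six motion summaries; optionally age) are removed
across subjects by per-feature OLS with an intercept; the intercept is
retained in the features. The regressor exposes separate fit/transform
so the protocol can estimate coefficients on training subjects only.
The medication-robustness variant drops every pair involving a named
motor component plus one named extra pair (36 → 27 features for nine
networks).

## Group statistics

Within-group one-sample t-tests and a between-group two-sample t-test
per pair, on Fisher-z values, with Benjamini–Hochberg FDR at q = 0.05.
Pooled-variance (Student) is the default — the groups are equal-sized by
design — with Welch behind a flag. Zero-variance columns fall back to
the degenerate convention (p = 0 for a nonzero mean difference, 1
otherwise, with a warning). These statistics are descriptive only; the
classification stage never consumes them, so no selection bias enters
the classifier evaluation.

## Classification protocol

The cohort is split once, stratified, into 16+16 training and 12+12
test subjects. Group ICA, component selection, nuisance-regression
coefficients, and hyperparameter selection use training subjects only;
an independent ICA is fitted on the test subjects and matched (with sign
alignment) to the training components before test features are
extracted. Hyperparameters are chosen by leave-one-out cross-validation
over the 32 training subjects; grids are ordered simple-to-complex and
ties resolve toward the simpler model. Performance on the 24 held-out
subjects is reported per classifier as the confusion matrix, accuracy,
sensitivity, specificity, PPV, NPV (undefined ratios are NaN, never 0),
and the Wilson score interval on accuracy.

The roster (equal class priors throughout): linear and quadratic
Gaussian discriminants (ridge-regularized when a covariance is singular,
as happens with 36 features and 32 subjects), Fisher's linear
discriminant, logistic regression, the classic perceptron, linear SVM,
k-nearest neighbors (Euclidean), Gaussian naive Bayes, a greedy binary
decision tree (information-gain or univariate-Fisher split score,
minimum leaf 2, fully grown; zero-gain ties split at the most balanced
threshold so parity problems remain solvable), a one-hidden-layer MLP
trained by plain gradient-descent backpropagation with a fixed epoch
count and seed, an RBF network (k-means centers, shared width, ridge
least-squares output), and kernel SVMs with the squared-exponential RBF
kernel (the exponential unsquared-norm form is selectable) and the
inhomogeneous polynomial kernel. The SVMs and logistic regression are
backed by scikit-learn's convex solvers and cross-checked against a
quadratic-programming oracle on tiny problems in the test suite; the
closed-form classifiers are implemented directly.

## Problem sizes and numerical choices

Desk-scale runs use grids of ~1000 voxels, 100–200 timepoints, and 4–12
components; at these sizes a full end-to-end protocol takes seconds and
the complete recovery suites run in minutes. The subject-level PCA
dimension may be reduced below the 80 default for such runs (it only
needs to dominate the true component count; the recovery results are
unchanged). Null calibration uses 500 small cohorts evaluated at the
time-course level — the t/FDR stage consumes features identically
whether they came through voxel mixing and ICA or not, and the
voxel/ICA path is exercised separately.

Fixed numerical conventions: ridge bump 1e-6 (relative) on singular
covariances; variance floor 1e-9 in naive Bayes; KNN ties resolve by
training order; every stochastic operation takes an explicit seed and
the protocol records all derived seeds in its provenance block.

## Known limitations

* The generator's stationarity and exact-covariance construction make
  recovery tests sharper than real data would allow; effect sizes for
  group differences are configuration, not estimates.
* MDL order selection uses the i.i.d.-sample likelihood; with strongly
  smoothed data it is known to over-estimate the order.
* The greedy decision tree only prunes via the minimum leaf size; no
  cost-complexity pruning.
* Only two-class problems are supported, matching the study design.
* One resting condition only; no task/rest contrasts.
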