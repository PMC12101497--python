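# Methods

## Overview

`wmcpm` implements a connectome-based predictive-modeling (CPM) pipeline for
working-memory components: per-subject behavioral capacities are scored and
combined into composite component scores; resting-state node time series are
turned into Fisher-z connectivity edge features; a leave-one-out
cross-validated linear support-vector regression (SVR) with nested
feature selection predicts each component from the edges; permutation tests
with Benjamini–Hochberg FDR establish significance; consensus predictive
edges are aggregated into network-level importance measures; and virtual
lesions test each network's necessity. Because no suitable public dataset
accompanies this design, the package ships a synthetic-data generator with
known ground truth, and the test suite validates the entire chain on it.

## Behavioral scoring

Change-detection capacity uses Cowan's estimator K = S(H − F), with set size
S, hit rate H and false-alarm rate F; a subject's capacity for a task is
K_max over its load conditions. Multiple-object tracking uses Scholl's
tracked capacity K = S(2P − 1) with tracking accuracy P. Before
standardization, each task's score vector is limited once to the grand mean
± 3 SD (cutoffs frozen from the first pass, so the operation is idempotent;
a constant vector is returned unchanged). z-scores use the sample SD
(n − 1). Composites are unweighted means of member z-scores; second-order
components (e.g. EVENT = ½(BM + NBM)) are unweighted means of first-order
composites. Accuracy-based tasks enter as plain proportions, z-scored like
capacities, with no logit transform.

## Connectivity features

Edges are Pearson correlations between node time courses, Fisher-z
transformed (arctanh). Correlations of exactly ±1 — duplicated series, a
data defect — are clipped to ±(1 − 1e−7) with a warning instead of aborting
a cohort run. Features are the strict upper triangle in a fixed, invertible
enumeration: 0-based, row-major, (0,1), (0,2), …, (n−2, n−1), declared once
in `EdgeIndexMap` and used identically by prediction, importance, and
lesioning. A 268-node atlas yields 35,778 edges. No nuisance regression,
filtering, or global-signal handling is performed here; the module assumes
cleaned time series.

## Prediction procedure

For each left-out subject, an epsilon-SVR (linear kernel, C = 1,
ε = 0.1, stopping tolerance 1e−3) is fitted on the remaining subjects over
all edges; edges are ranked by |weight| descending, ties broken by lower
edge index. The top q‰ of edges is kept — count = floor(n_edges·q/1000),
minimum 1, which reproduces the 35/322 endpoints for 35,778 edges at 1‰/9‰
(rounding would give 36) — and a fresh SVR fitted on the subset predicts the
held-out subject. Accuracy is Pearson's r between predicted and observed
scores. Feature standardization is off by default (Fisher-z edges share a
scale); when enabled, means and SDs come from the training fold only.

Significance: each permutation shuffles the scores and reruns the entire
nested procedure, including per-fold re-selection. The primary p is the
proportion of permuted r exceeding the observed r (it can be exactly 0); a
bias-corrected (k+1)/(n+1) variant is reported alongside. One master seed
spawns an independent stream per permutation, so results do not depend on
execution order. BH-FDR runs over the analysis family (e.g. thresholds ×
components for a multi-component analysis; thresholds × networks within one
lesion scan); families never pool across scans.

### SVR solver

The solver is the classic libsvm SMO algorithm for epsilon-SVR (expanded
2n-variable dual, second-order working-set selection, identical stopping
rule), compiled with numba and operating on a precomputed subjects ×
subjects Gram matrix. The feature matrix never changes across permutations,
so the Gram matrix is computed once per dataset; fold weights are recovered
in a single matrix product, and refits on the nested top-k subsets reuse
incrementally accumulated sub-Grams with warm starts that use only
fold-internal information (a warm start shared across folds would let the
held-out subject's score steer the solver path — a leakage channel the test
suite checks explicitly). Unit tests verify agreement with `sklearn.svm.SVR`
(same algorithm family) on dual coefficients, intercepts, predictions, and
weight rankings to solver tolerance. Two solutions that both satisfy the
stopping rule can differ slightly (dual-objective gap below ~0.05 on
unit-scale problems); all results are deterministic for a fixed seed and
configuration.

## Network importance

Consensus edges at a threshold are those selected in every LOOCV fold; their
weight is the sum over all folds of the absolute ranking-fit weight.
Between-network strength is Edge_IJ = Σ |edge weight| over consensus edges
linking networks I and J; within-network edges populate the diagonal
Edge_II, which the relative-degree formula counts exactly as written:
RD_I = Σ_J binarize(Edge_IJ) / Σ_I Σ_J binarize(Edge_IJ). RD sums to 1
whenever any Edge entry is nonzero (asserted on every run). Node degree
within a network counts unordered consensus edges incident to each node
(an edge wholly inside a network adds 1 to each endpoint), ranked
descending with ties by node id.

Because RD binarizes network-pair hits, a dense consensus set (hundreds of
edges at liberal thresholds) saturates the binarization and flattens RD
across networks. The pipeline therefore computes importance at the sparsest
BH-significant threshold (falling back to the best-r threshold when nothing
is significant). A structural consequence of binarization worth knowing:
when every true edge lies inside one network, that network contributes
exactly one nonzero pair (its diagonal), so its RD ties with — rather than
strictly exceeds — any other network touched by a single stray consensus
edge; localization claims should therefore be phrased as "attains the
maximal RD", ties included.

## Virtual lesions

Lesioning a network retains only edges with both endpoints outside it —
(n−k)(n−k−1)/2 edges after removing k of n nodes — and re-runs the full
prediction with per-mille counts recomputed from the reduced edge total
(selection stays proportional, mirroring the per-mille framing of the
original analysis). The scan's FDR family is thresholds × lesioned networks.

## ROI time courses

An ROI signal is segmented at trial onsets (sample time = index · TR from
onset, 0-based), averaged within condition, and converted to percent signal
change against a designated baseline condition, psc = (cond − base)/base.
The delay-phase summary is the mean over samples whose time falls in the
inclusive window 13–15 s. Trials running past the series end are dropped
with a warning; losing all of a condition's trials is an error.

## Synthetic data generator

The generator defines the study conditions the suite validates:

* **Atlas** — 268 nodes in 10 networks (default sizes 29, 34, 20, 28, 50,
  18, 9, 27, 33, 20; the 20-node cerebellum network hosts the signal by
  default). A seeded permutation interleaves networks through the node
  ordering.
* **Time series** — stationary Gaussian, T = 240 timepoints, block
  covariance with rho_within = 0.3 and rho_between = 0. Between-network
  correlation is deliberately zero: a shared background correlation acts as
  a global latent factor whose subject-level sampling fluctuations couple
  all edges, which would let a signal confined to one network remain
  predictable from every other network and defeat lesion-specificity
  testing. No temporal autocorrelation (the pipeline consumes only static
  correlation matrices); an AR option is out of scope.
* **Behavior** — y = Σ w_e x_e + N(0, σ), with 30 signal edges drawn inside
  the target network (both endpoints by default; an either-endpoint mode is
  a flag) and weights from Uniform(0.5, 1.5) with a common sign. The common
  sign keeps each edge's marginal association from cancelling across
  positively correlated within-network edges, so individual edges stay
  detectable — the property the recovery suite is designed to exercise.
  SNR is defined as sd(noiseless predictor)/σ on the realized cohort;
  default 1.5.
* **Trials** — whole-display guessing model: with d = min(K/S, 1),
  hits ~ Bin(n_change, d + (1−d)g) and false alarms ~ Bin(n_nochange,
  (1−d)g), which makes the Cowan estimator unbiased with
  E[S(H−F)] = min(K, S).

What the generator does not emulate: hemodynamics, temporal autocorrelation,
head motion, physiological noise, site effects, non-Gaussian edge
distributions, or nonlinear brain-behavior coupling. Passing tests therefore
demonstrate the statistical machinery — leakage-free nested selection,
calibrated permutation nulls, correct importance bookkeeping, lesion
specificity under a known truth — not performance on real fMRI data.

## Problem sizes used by the test suite and acceptance script

The validation runs use scaled-down Monte-Carlo sizes chosen as a
single-CPU budget: 20 replicates of the 103-subject study-scale analysis at
200 permutations per threshold (the full analysis in the original design
uses 1000); a null-calibration study of 100 replicates × 99 permutations at
30 subjects/20 nodes; one full 10-network lesion scan at 100 permutations;
estimator-recovery checks averaging 30 draws of 2,000 trials. The
acceptance script runs one study-scale replicate (100 permutations, lesion
scan at 50) and prints each quantity with the problem size it used.

## Known limitations

* LOOCV with per-fold selection is noisy at small n: even noiseless planted
  signals are recovered at r ≈ 0.9, not 1.0, because individual folds can
  miss weakly weighted edges.
* The permutation p at B permutations has resolution 1/B; the primary
  strictly-greater definition can return exactly 0.
* Composite construction assumes complete task tables; missing scores raise
  rather than impute.
* Confirmatory factor analysis / SEM of the task battery is out of scope;
  composites are unweighted z-score means.
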