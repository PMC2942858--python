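# Methods

`classpower` estimates the statistical power of high-dimensional two-class
biomarker discovery studies by Monte-Carlo simulation.  A "study" measures
`n_features` molecular features (default 1000) on `n_case + n_control`
subjects; a small fixed subset of features (the biomarkers, fraction *k*)
differs in class-conditional mean by `delta`, and the analysis must both
find a discriminating feature subset and certify that the resulting
classifier beats chance.  Power is the probability that this certification
succeeds at significance level 0.05.

## Generative models

**Gaussian.** Every feature is N(0, sigma^2) for controls and noise
features, and N(delta, sigma^2) for case biomarkers, with sigma^2 = 0.2.
Effect sizes are quoted as delta/sigma, so the delta grid 0, 0.05, ..., 0.50
corresponds to effects 0, 0.11, ..., 1.12; e.g. delta = 0.15 is effect 0.34.

**Gaussian/uniform mixture (skewed).** Each value is N(mu, sigma^2) with
probability 0.9 and Uniform(mu + c1 sigma, mu + c2 sigma) with probability
0.1, with c1 = 3.0, c2 = 6.7.  The location mu is solved from
E(X) = mu + 0.1 sigma (c1 + c2)/2 so the control mean is 0 and the case
biomarker mean is `delta`.  The closed-form moments of this mixture are
variance 0.626 and skewness 1.516 (`mixture_moments`); note that effect-size
*labels* for mixture scenarios follow the convention delta/sqrt(0.8) — the
variance quadrupling relative to the Gaussian setting — so mixture
delta = 0.25 is labeled effect 0.28.  The labeling convention and the exact
mixture variance disagree by design; the generator follows the stated
distributional equations, and the labels follow the quoted convention.

**Correlated biomarkers (Gaussian only).** Compound-symmetric correlation
rho among the biomarker columns within both classes, marginal variance
unchanged; noise stays independent.  A correlated mixture is rejected rather
than invented.

One root seed drives everything; per-dataset and per-CV child streams are
derived by keyed `SeedSequence` spawning (`child_seeds`), so any dataset is
reproducible independent of execution order or worker count.

## Classifiers

* **KNN** — 5 nearest neighbours, Euclidean distance (scikit-learn).
  Score: case-neighbour fraction.
* **NSC** (nearest shrunken centroid, PAM-style) — implemented here in
  full: pooled within-class sd `s_i` (denominator n − 2), fudge
  `s0 = median(s_i)`, `m_k = sqrt(1/n_k − 1/n)`, standardized differences
  `d_ik = (xbar_ik − xbar_i)/(m_k (s_i + s0))` soft-thresholded at Delta;
  prediction minimises `sum_i (x_i − xbar'_ik)^2/(s_i + s0)^2 − 2 log pi_k`.
  Score: control-minus-case discriminant difference.
* **RF** — scikit-learn random forest (500 fully grown trees, mtry =
  ceil(sqrt(p))), wrapped to expose per-tree out-of-bag indices.  Score:
  case vote fraction.
* **SVM** — RBF kernel, C = 1, bandwidth gamma = 1/median squared pairwise
  distance of a training subsample (the classical median heuristic, standing
  in for "estimated from the data").  Score: signed decision value.

Class-prior handling: `prior_policy="equal"` sets pi_k = 1/2 in the NSC
discriminant and balanced class weights in RF tree growing; KNN and SVM are
never reweighted.  With balanced classes the two policies are identical and
the implementation takes the unweighted path so the equivalence is exact.

Ties on the decision score (possible only at exact discriminant equality,
e.g. full shrinkage under equal priors) resolve toward the case class —
mirroring first-factor-level tie behaviour of the R classification stack.
This choice is consequential only in the unbalanced scenario, where the
fully shrunken classifier otherwise degenerates to majority voting; see
"Knife-edge scenarios" below.

## Feature elimination

KNN/RF/SVM: recursive elimination removing max(1, floor(0.01 m)) of the
current m features while m > 100, then one per step to a single feature.
Importance is *out-of-bag permutation importance from a random-forest fit*,
recomputed at every step on the surviving features of the current training
set (for all three classifiers — the forest is the importance engine even
when the classifier is KNN or SVM).  Permuting a feature can only change a
tree's predictions if the tree splits on it, so only split features are
traversed (a numba kernel); unused features keep importance 0.  Negative
importances are kept; ranking ties break toward the lower feature index.

NSC: the elimination path is the 30-point shrinkage grid, equally spaced
from 0 to max |d_ik|.  The grid is computed once per dataset and shared by
all CV folds, so fold curves align by threshold value — this mirrors the
reference PAM cross-validation, which cross-validates the full-data fit's
threshold vector.  (`run_rfe` on a single training set computes that set's
own grid.)

## Performance evaluation and power

One stratified 4-way partition per dataset.  Each fold's 75% training
portion runs its own elimination path; every step is scored on the held-out
25% by accuracy or rank-form (Mann-Whitney, ties one half) AUC; curves are
averaged across folds by schedule position; the dataset statistic is the
curve maximum (ties to the earliest step, i.e. more features).  This maximum
is selection-biased upward even on pure noise, so significance is calibrated
against a null distribution: 100 all-noise datasets run through the
identical pipeline.  A dataset's p-value is the fraction of null statistics
>= its observed statistic (ties count toward p); power is the fraction of
100 alternative datasets with p <= 0.05, with a Wald binomial 95% interval
(which reproduces every printed interval at n = 100 to two decimals).  The
null keeps everything about the design except the signal (sample sizes,
feature count, family, biomarker correlation); one null is reused across
effect sizes sharing (classifier, metric, n, k, family, rho).

The independent-test variant selects the best schedule position by CV,
refits on the full training data — at the shared-grid threshold for NSC, or
on fold 1's surviving feature set for the others — and scores one fresh
400-subject (200/200) test set.

The idealized ceiling is the Bayes-rule accuracy
Phi((delta/(2 sigma)) sqrt(p)) for p independent equal-effect Gaussian
biomarkers and equal priors (`theory.bayes_accuracy`).

## Data characterization

For a user matrix (samples x features, log scale assumed, no transform
applied): per-feature effect size |mean1 − mean2| / pooled within-class sd;
within-class skewness with population (1/n) moments, averaged over the two
classes; and the percentage of features whose Anderson-Darling normality
p-value *and* q-value both fall below 0.05 within a class, averaged over
classes.  q-values use a Storey-style pFDR estimate (pi0 at lambda = 0.5)
with Benjamini-Hochberg available as `method="bh"`.

## Problem sizes and numerical choices

* NSC power scenarios run at full scale (100 null + 100 alternative
  datasets, 1000 features, the study's sample sizes); one scenario takes
  tens of seconds.
* The RF acceptance check runs a scaled protocol chosen for tractability on
  a single core: 20 null + 25 alternative datasets, 100-tree forests, and a
  coarse elimination schedule removing 5% of the initial feature count per
  step down to 50 features, then halving (`coarse_schedule`).  Its result is
  compared with the full-scale reported value within two binomial standard
  errors at n = 25.
* Type-I-error calibration for all classifier/metric pairs runs at reduced
  dimension (6 features, 12 per class, 10-tree forests); under the null the
  property is scale-free because alternative and calibration datasets are
  exchangeable.
* Quantiles use linear interpolation between order statistics
  (`numpy.percentile` default); `n_null < 20` is rejected as unstable.
* Zero-variance features are kept finite by the s0 fudge in NSC and
  reported as missing (NaN) in characterization.

## What the simulations do and do not emulate

The generators reproduce the dimensionality, sparsity of signal, noise
level, skew/outlier structure, class imbalance, and biomarker correlation
patterns typical of log-scale 'omics' intensity matrices.  They assume a
common within-class variance for every feature, at most compound-symmetric
dependence confined to biomarkers, no batch or platform effects, no missing
values, and exactly two outcome classes.  Passing tests therefore speak to
method behaviour under these idealized conditions, not to any particular
real platform.

## Knife-edge scenarios and known limitations

Two reported operating points sit on thin margins and are sensitive to
implementation micro-choices that the available sources do not pin down:

* **Unbalanced classes (100/200, equal priors).**  At full shrinkage all
  discriminants are exactly equal, so the tie rule decides between
  all-case (accuracy 1/3) and all-control (accuracy 2/3) predictions; the
  null 95th percentile and the alternative distribution sit within a few
  thousandths of each other, so the estimated power swings by tens of
  points with that single convention.
* **Correlated biomarkers (rho = 0.5).**  This implementation's shrunken
  centroid operates close to the Bayes accuracy ceiling for the correlated
  design (Phi computed from the equicorrelated SNR), yielding higher power
  than the reported value; generating the correlation with an added shared
  component (inflating biomarker variance) instead of a
  correlation-preserving transform would reproduce the lower reported
  number, but contradicts the stated constant within-class variance.

Both scenarios are implemented as specified and their acceptance
comparisons are reported as measured.  Monte-Carlo uncertainty at 100
datasets is about +/-5 power points (1 SE) before accounting for
variability of the null threshold itself.

A related limitation: *exact* recovery of the full biomarker set by the
elimination path (every biomarker surviving to the step with exactly
k features) is far from certain at modest effect sizes, because the final
one-at-a-time elimination steps depend on permutation-importance draws
whose noise does not vanish with more data — at effect 0.56 the measured
exact-set recovery rate is roughly 40-70% depending on forest size, even
though per-biomarker survival is high and classification power at that
effect is essentially 100%.  Detecting a significant classifier and
pinning down the exact biomarker set are different goals with very
different sample-size demands.
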