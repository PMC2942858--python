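# classpower

Monte-Carlo statistical power for high-dimensional two-class biomarker
discovery studies.

## The problem

'Omics' discovery studies measure ~10^3 molecular features per subject on
tens to hundreds of subjects, hoping to find a feature subset and a
classifier that separate two phenotype classes (cases vs controls).  The
analysis pipeline — recursive feature elimination wrapped around a
classifier, tuned by cross-validation — itself consumes information, so
classical per-feature power formulas badly misestimate the sample size such
a study needs.  `classpower` answers the design question by simulating the
*entire* pipeline:

1. simulate datasets with n subjects per class, p features of which a
   fraction k are biomarkers shifted by delta (Gaussian or a skewed
   Gaussian/uniform mixture, optionally correlated biomarkers or unbalanced
   classes);
2. run a classifier — k-nearest neighbours (KNN), nearest shrunken
   centroids (NSC/PAM), random forests (RF), or an RBF support-vector
   machine (SVM) — with recursive feature elimination under a single
   stratified 4-fold cross-validation, taking the **maximum fold-averaged
   accuracy or AUC over the elimination path** as the dataset's statistic;
3. calibrate that statistic against its null distribution from 100
   all-noise datasets (95th percentile ⇒ p ≤ 0.05);
4. report **power** = the fraction of simulated alternative datasets that
   are significant, with a Wald binomial confidence interval.

For KNN, RF and SVM the elimination removes the least important 1% of
features per step (then one at a time below 100 features), ranked by
out-of-bag permutation importance from a random-forest fit; for NSC the
path is a 30-point centroid-shrinkage threshold grid.  The idealized
ceiling Φ((δ/2σ)√p) (Bayes-rule accuracy for p independent equal-effect
Gaussian biomarkers) is available for comparison, and a `characterize`
module computes the statistics used to place a real feature matrix in this
parameter space (per-feature effect sizes |μ₁−μ₂|/σ, within-class skewness,
percent non-Gaussian by Anderson–Darling + q-value).

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
import classpower as cp

# n=150 per class, 1000 features, 10 biomarkers at effect size 0.34
design = cp.SimulationDesign(n_case=150, n_control=150, n_features=1000,
                             n_biomarkers=10,
                             delta=cp.effect_to_delta(0.34, "gaussian"))
spec = cp.ClassifierSpec("nsc")

null = cp.build_null(spec, design, "accuracy", n_null=100, seed=11)
res = cp.estimate_power(spec, design, "accuracy", null=null,
                        n_sim=100, seed=12)
print(f"null 95th percentile accuracy: {null.threshold:.3f}")
print(f"power: {res.power:.2f}  95% CI ({res.ci_low:.2f}, {res.ci_high:.2f})")
print(f"mean best CV accuracy: {res.best_metrics.mean():.3f}")
```

prints (about a minute on one core):

```
null 95th percentile accuracy: 0.587
power: 0.87  95% CI (0.80, 0.94)
mean best CV accuracy: 0.630
```

So a 150-per-class study with ten such biomarkers detects a significant
classifier most of the time — around 80% across seeds, with roughly
±5-point Monte-Carlo spread at 100 datasets — even though the best
cross-validated accuracy is only ~63% against a null threshold of ~59%;
the selection-inflated null is why calibration matters.  The same run with
`delta=0` gives power ≈ 0.05 (the type-I error), and the closed-form
optimum `cp.bayes_accuracy(cp.BayesSetting(0.34, 10))` ≈ 0.70 bounds what
any classifier could achieve on these data.

The same sweep from the shell:

```bash
classpower simulate-power --classifier nsc --effect 0.34 --n-per-class 150 \
    --k 0.01 --seed 11 --out power.csv
classpower bayes --effect 0.34 --p 10
classpower characterize my_matrix.tsv --label-column class --out summary.csv
```

or a YAML scenario file via `classpower simulate-power --config experiments.yaml`.

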