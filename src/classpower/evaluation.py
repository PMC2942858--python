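"""Cross-validated performance of an RFE-wrapped classifier.

One dataset is scored by a single stratified 4-way partition: each fold's
75% training portion runs its own elimination path, every path step is
evaluated on the held-out 25%, the metric is averaged across folds by
schedule position, and the dataset's summary statistic is the *maximum* of
that averaged curve.  Because the maximum is taken over a selection path, the
statistic is optimistically biased even on pure-noise data — which is exactly
why power estimation calibrates it against an all-noise null distribution
rather than against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifiers import (
    ClassifierSpec,
    _binary,
    _labels,
    fit_predict_score,
    nsc_fit,
    nsc_threshold_grid,
    soft_threshold,
)
from .datasets import LabeledDataset
from .rfe import EliminationPath, _rfe_steps, elimination_schedule

METRIC_KINDS = ("accuracy", "auc")


@dataclass
class CvResult:
    """Fold-averaged metric along the elimination path for one dataset."""

    metric_kind: str
    curve: np.ndarray            # fold-averaged metric per schedule position
    best_metric: float
    best_step: int               # earliest position attaining the maximum
    fold_paths: list[EliminationPath]


def stratified_folds(y: np.ndarray, n_folds: int = 4, seed: int = 0) -> np.ndarray:
    """A single random stratified n_folds-way partition; returns fold ids."""
    y01 = _binary(y)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2**32 - 1))
    fold_ids = np.empty(len(y01), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(y01), y01)):
        fold_ids[test_idx] = f
    return fold_ids


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties counted 1/2."""
    y01 = _binary(y_true)
    n_case = int(y01.sum())
    n_control = len(y01) - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError("AUC needs both classes in the truth vector")
    r = rankdata(scores)
    return float((r[y01 == 1].sum() - n_case * (n_case + 1) / 2.0)
                 / (n_case * n_control))


def compute_metric(
    metric_kind: str,
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    scores: Optional[np.ndarray] = None,
) -> float:
    if metric_kind == "accuracy":
        return float(np.mean(np.asarray(true_labels) == np.asarray(predicted_labels)))
    if metric_kind == "auc":
        if scores is None:
            raise ValueError("AUC requires scores")
        return auc_rank(true_labels, scores)
    raise ValueError(f"unknown metric {metric_kind!r}")


def _nsc_fold_curves(spec, train, test_X, y_test01, grid):
    """Accuracy and AUC per shrinkage threshold for one fold (one NSC fit).

    ``grid`` is the dataset-level threshold grid, shared by all folds so the
    fold curves align by threshold value (the reference PAM cross-validation
    behaves the same way).
    """
    model = nsc_fit(train, 0.0, spec.prior_policy)
    sw = model.pooled_sd + model.s0
    acc = np.empty(len(grid))
    auc = np.empty(len(grid))
    for i, t in enumerate(grid):
        d_shrunk = soft_threshold(model.d, t)
        cent = model.overall_centroid + model.m_k[:, None] * sw * d_shrunk
        disc = np.empty((test_X.shape[0], 2))
        for k in range(2):
            z = (test_X - cent[k]) / sw
            disc[:, k] = np.einsum("ij,ij->i", z, z) - 2.0 * np.log(model.priors[k])
        scores = disc[:, 0] - disc[:, 1]
        pred01 = (scores >= 0).astype(int)
        acc[i] = np.mean(pred01 == y_test01)
        r = rankdata(scores)
        n1 = y_test01.sum()
        n0 = len(y_test01) - n1
        auc[i] = (r[y_test01 == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return acc, auc, model


def cv_metric_curves(
    spec: ClassifierSpec,
    data: LabeledDataset,
    seed: int = 0,
    n_folds: int = 4,
    schedule: Optional[list[int]] = None,
) -> dict:
    """Fold-averaged accuracy and AUC curves along the elimination path.

    The elimination fits are metric-independent, so both metrics come from
    one CV pass.  Returns ``{"accuracy": curve, "auc": curve,
    "positions": schedule-or-grid, "fold_paths": [...]}``.
    """
    rng = np.random.default_rng(seed)
    fold_ids = stratified_folds(data.y, n_folds, int(rng.integers(2**31)))
    if spec.kind == "nsc":
        n_steps = spec.nsc_n_thresholds
        # one grid per dataset, shared across folds (pamr-style CV alignment)
        positions = nsc_threshold_grid(data, spec.nsc_n_thresholds)
    else:
        sched = schedule if schedule is not None else elimination_schedule(
            data.n_features
        )
        n_steps = len(sched)
        positions = np.asarray(sched)

    acc_sum = np.zeros(n_steps)
    auc_sum = np.zeros(n_steps)
    fold_paths: list[EliminationPath] = []
    for f in range(n_folds):
        tr = fold_ids != f
        te = ~tr
        train = LabeledDataset(X=data.X[tr], y=data.y[tr])
        test_X = data.X[te]
        y_te01 = _binary(data.y[te])
        fold_seed = int(rng.integers(2**31))
        if spec.kind == "nsc":
            acc, auc, model = _nsc_fold_curves(
                spec, train, test_X, y_te01, positions
            )
            sets = [
                np.where(np.any(soft_threshold(model.d, t) != 0.0, axis=0))[0]
                for t in positions
            ]
            fold_paths.append(
                EliminationPath(kind="nsc", schedule=positions, feature_sets=sets)
            )
        else:
            acc = np.empty(n_steps)
            auc = np.empty(n_steps)
            sets = []
            for i, (surv, forest) in enumerate(
                _rfe_steps(spec, train, fold_seed, list(positions))
            ):
                sets.append(surv)
                if spec.kind == "rf":
                    scores = forest.case_fraction(test_X[:, surv])
                    pred01 = (scores >= 0.5).astype(int)
                else:
                    sub = LabeledDataset(X=train.X[:, surv], y=train.y)
                    labels, scores = fit_predict_score(
                        spec, sub, test_X[:, surv], seed=fold_seed + i
                    )
                    pred01 = _binary(labels)
                acc[i] = np.mean(pred01 == y_te01)
                r = rankdata(scores)
                n1 = y_te01.sum()
                n0 = len(y_te01) - n1
                auc[i] = (r[y_te01 == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
            fold_paths.append(
                EliminationPath(
                    kind=spec.kind, schedule=np.asarray(positions),
                    feature_sets=sets,
                )
            )
        acc_sum += acc
        auc_sum += auc
    return {
        "accuracy": acc_sum / n_folds,
        "auc": auc_sum / n_folds,
        "positions": positions,
        "fold_paths": fold_paths,
    }


def cv_best_metric(
    spec: ClassifierSpec,
    data: LabeledDataset,
    metric_kind: str = "accuracy",
    seed: int = 0,
    n_folds: int = 4,
    schedule: Optional[list[int]] = None,
) -> CvResult:
    """Maximum fold-averaged metric over the elimination path.

    Ties resolve to the earliest schedule position (the step with more
    features / the smaller shrinkage threshold).
    """
    if metric_kind not in METRIC_KINDS:
        raise ValueError(f"unknown metric {metric_kind!r}")
    curves = cv_metric_curves(spec, data, seed, n_folds, schedule)
    curve = curves[metric_kind]
    best_step = int(np.argmax(curve))
    return CvResult(
        metric_kind=metric_kind,
        curve=curve,
        best_metric=float(curve[best_step]),
        best_step=best_step,
        fold_paths=curves["fold_paths"],
    )


def independent_test_metric(
    spec: ClassifierSpec,
    train_data: LabeledDataset,
    test_data: LabeledDataset,
    metric_kind: str = "accuracy",
    seed: int = 0,
    n_folds: int = 4,
    schedule: Optional[list[int]] = None,
) -> float:
    """Evaluate the CV-selected model once on an independent test set.

    The best schedule position is chosen by ``cv_best_metric``; the final
    model is refit on the full training data at that position — using the
    first fold's surviving feature set (KNN/RF/SVM) or the full-training-data
    threshold grid value at that position (NSC).
    """
    if test_data.n_features != train_data.n_features:
        raise ValueError("train and test feature counts differ")
    result = cv_best_metric(spec, train_data, metric_kind, seed, n_folds, schedule)
    if spec.kind == "nsc":
        grid = nsc_threshold_grid(train_data, spec.nsc_n_thresholds)
        model = nsc_fit(train_data, float(grid[result.best_step]), spec.prior_policy)
        scores = model.decision_scores(test_data.X)
        labels = _labels(scores >= 0)
    else:
        surv = result.fold_paths[0].feature_sets[result.best_step]
        sub = LabeledDataset(X=train_data.X[:, surv], y=train_data.y)
        labels, scores = fit_predict_score(
            spec, sub, test_data.X[:, surv], seed=seed + 1
        )
    return compute_metric(metric_kind, test_data.y, labels, scores)
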