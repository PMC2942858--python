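"""Recursive feature elimination schedules and per-training-set paths.

For KNN, RF and SVM the path removes the least important 1% of the current
features per step (at least one) while more than 100 remain, then exactly one
per step down to a single feature; importance is recomputed from a fresh
random-forest fit at every step.  For the NSC classifier the elimination path
is a grid of shrinkage thresholds (equally spaced from 0 to max |d_ik| of
this training set), which plays the equivalent role: raising the threshold
shrinks more standardized centroid differences to zero and so drops features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .classifiers import (
    ClassifierSpec,
    _Forest,
    _binary,
    fit_forest,
    nsc_fit,
    nsc_threshold_grid,
    rank_features,
    soft_threshold,
)
from .datasets import LabeledDataset


@dataclass
class EliminationPath:
    """One training set's elimination path.

    ``schedule`` is a strictly decreasing list of feature counts (KNN/RF/SVM)
    or a strictly increasing threshold grid (NSC); ``feature_sets`` holds the
    surviving feature indices at each step, nested across steps.
    """

    kind: str
    schedule: np.ndarray
    feature_sets: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.schedule)


def elimination_schedule(p_start: int) -> list[int]:
    """Feature counts visited by the elimination procedure, ending at 1.

    While more than 100 features remain, each step removes
    max(1, floor(0.01 * current)); at or below 100, one feature per step.
    """
    if p_start < 1:
        raise ValueError("p_start must be >= 1")
    counts = [p_start]
    p = p_start
    while p > 1:
        drop = max(1, p // 100) if p > 100 else 1
        p -= drop
        counts.append(p)
    return counts


def coarse_schedule(p_start: int, step_fraction: float = 0.05) -> list[int]:
    """Coarse schedule for scaled-down experiments.

    Removes ``step_fraction`` of the *initial* feature count per step down to
    that step size, then halves down to 1.  Used where the one-at-a-time tail
    of the full schedule is too expensive.
    """
    if p_start < 1:
        raise ValueError("p_start must be >= 1")
    step = max(1, int(step_fraction * p_start))
    counts = [p_start]
    p = p_start
    while p > step:
        p -= step
        counts.append(p)
    while p > 1:
        p //= 2
        counts.append(p)
    return counts


def _rfe_steps(
    spec: ClassifierSpec,
    train: LabeledDataset,
    seed: int,
    schedule: Optional[list[int]] = None,
) -> Iterator[tuple[np.ndarray, _Forest]]:
    """Yield (surviving feature indices, forest fitted on them) per step.

    The forest serves both as the importance source for the next elimination
    and — when ``spec.kind == 'rf'`` — as the classifier evaluated at this
    step, so RF never fits twice.
    """
    if schedule is None:
        schedule = elimination_schedule(train.n_features)
    rng = np.random.default_rng(seed)
    surviving = np.arange(train.n_features)
    for i, p_target in enumerate(schedule):
        assert len(surviving) == p_target
        sub = LabeledDataset(
            X=train.X[:, surviving], y=train.y,
            biomarker_indices=np.empty(0, dtype=int),
        )
        forest = fit_forest(sub, spec, int(rng.integers(2**31)))
        yield surviving, forest
        if i + 1 < len(schedule):
            imp = forest.oob_permutation_importance(
                sub.X, _binary(sub.y), int(rng.integers(2**31))
            )
            keep = np.sort(rank_features(imp)[: schedule[i + 1]])
            surviving = surviving[keep]


def run_rfe(
    spec: ClassifierSpec,
    train: LabeledDataset,
    seed: int = 0,
    schedule: Optional[list[int]] = None,
) -> EliminationPath:
    """Compute the elimination path for one training set.

    For NSC, returns the 30-point (``spec.nsc_n_thresholds``) threshold grid
    with the features still active at each threshold; for the others, the
    nested surviving feature sets along the count schedule.
    """
    if spec.kind == "nsc":
        grid = nsc_threshold_grid(train, spec.nsc_n_thresholds)
        model = nsc_fit(train, 0.0, spec.prior_policy)
        sets = [
            np.where(np.any(soft_threshold(model.d, t) != 0.0, axis=0))[0]
            for t in grid
        ]
        return EliminationPath(kind="nsc", schedule=grid, feature_sets=sets)
    sets = [surv for surv, _ in _rfe_steps(spec, train, seed, schedule)]
    sched = schedule if schedule is not None else elimination_schedule(train.n_features)
    return EliminationPath(
        kind=spec.kind, schedule=np.asarray(sched), feature_sets=sets
    )
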