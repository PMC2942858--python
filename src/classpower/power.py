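"""Null-calibrated statistical power of an RFE-wrapped classifier.

The null distribution of the best cross-validated metric is built from
datasets in which every feature is noise (delta = 0); a dataset's p-value is
the fraction of null values at least as large as its observed statistic
(ties count, conservatively), so p <= 0.05 coincides with exceeding the null
95th percentile up to ties.  Power is the fraction of simulated alternative
datasets with p <= 0.05, reported with a Wald binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .datasets import SimulationDesign, child_seeds, generate_dataset
from .evaluation import cv_best_metric


@dataclass
class NullDistribution:
    """Best-metric values from all-noise datasets and their 95th percentile."""

    spec: ClassifierSpec
    design: SimulationDesign         # delta = 0 version
    metric_kind: str
    values: np.ndarray
    threshold: float                 # empirical 95th percentile

    @property
    def n_null(self) -> int:
        return len(self.values)


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_sim: int
    best_metrics: np.ndarray
    p_values: np.ndarray


def wald_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), clipped to [0, 1]."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return max(0.0, p_hat - half), min(1.0, p_hat + half)


def build_null(
    spec: ClassifierSpec,
    design: SimulationDesign,
    metric_kind: str = "accuracy",
    n_null: int = 100,
    seed: int = 0,
    schedule: Optional[list[int]] = None,
) -> NullDistribution:
    """Best-CV-metric null distribution from ``n_null`` all-noise datasets.

    ``design.delta`` is forced to 0; all other design aspects (sample sizes,
    feature count, distribution family, biomarker correlation) are kept, so
    the null matches the alternative's data-generating mechanism in
    everything but the signal.
    """
    if n_null < 20:
        raise ValueError("n_null < 20 makes the 95th percentile unstable")
    null_design = design.as_null()
    data_seeds = child_seeds(seed, "null", n_null)
    cv_seeds = child_seeds(seed, "cv", n_null)
    values = np.empty(n_null)
    for i in range(n_null):
        data = generate_dataset(replace(null_design, seed=int(data_seeds[i])))
        values[i] = cv_best_metric(
            spec, data, metric_kind, int(cv_seeds[i]), schedule=schedule
        ).best_metric
    threshold = float(np.percentile(values, 95))  # linear-interpolation quantile
    return NullDistribution(
        spec=spec, design=null_design, metric_kind=metric_kind,
        values=values, threshold=threshold,
    )


def dataset_p_value(observed: float, null: NullDistribution) -> float:
    """Fraction of null values >= observed (ties counted toward p)."""
    if not np.isfinite(observed):
        raise ValueError("observed metric must be finite")
    if null.n_null == 0:
        raise ValueError("empty null distribution")
    return float(np.mean(null.values >= observed))


def estimate_power(
    spec: ClassifierSpec,
    design: SimulationDesign,
    metric_kind: str = "accuracy",
    null: Optional[NullDistribution] = None,
    n_sim: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    schedule: Optional[list[int]] = None,
) -> PowerResult:
    """Power = fraction of simulated datasets significant against the null.

    Alternative datasets draw from a seed stream independent of the null's.
    A delta = 0 design measures the type-I error rate instead of power.
    """
    if null is None:
        null = build_null(spec, design, metric_kind, seed=seed, schedule=schedule)
    data_seeds = child_seeds(seed, "alternative", n_sim)
    cv_seeds = child_seeds(seed + 1, "cv", n_sim)
    best = np.empty(n_sim)
    for i in range(n_sim):
        data = generate_dataset(replace(design, seed=int(data_seeds[i])))
        best[i] = cv_best_metric(
            spec, data, metric_kind, int(cv_seeds[i]), schedule=schedule
        ).best_metric
    p_values = np.array([dataset_p_value(b, null) for b in best])
    power = float(np.mean(p_values <= alpha))
    lo, hi = wald_ci(power, n_sim)
    return PowerResult(
        power=power, ci_low=lo, ci_high=hi, n_sim=n_sim,
        best_metrics=best, p_values=p_values,
    )


def results_row(
    scenario_id: str,
    spec: ClassifierSpec,
    design: SimulationDesign,
    metric_kind: str,
    effect_size: float,
    result: PowerResult,
    seed: int,
) -> dict:
    """One CSV row of a results table."""
    return {
        "scenario": scenario_id,
        "classifier": spec.kind,
        "metric": metric_kind,
        "n_case": design.n_case,
        "n_control": design.n_control,
        "n_features": design.n_features,
        "k": design.n_biomarkers / design.n_features,
        "effect_size": effect_size,
        "power": result.power,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n_sim": result.n_sim,
        "seed": seed,
    }


def results_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
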