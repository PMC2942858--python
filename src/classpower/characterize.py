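"""Data-characterization statistics for a two-class feature matrix.

Summaries used to position a real study within the simulation's parameter
space: per-feature effect size (standardized between-class mean difference),
average within-class skewness, and the percentage of features with
significantly non-Gaussian class-conditional distributions (Anderson-Darling
test with q-value multiplicity adjustment).  Features are assumed to already
be on the intended (typically log) scale; no transform is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

from .datasets import CASE, CONTROL


@dataclass
class FeatureSummary:
    """Per-feature statistics plus the dataset-level non-Gaussian percentage."""

    effect_size: np.ndarray           # |mean1 - mean2| / pooled within-class sd
    skewness: np.ndarray              # mean of the two within-class estimates
    normality_p: dict                 # class -> per-feature AD p-values
    normality_q: dict                 # class -> per-feature q-values
    percent_nongaussian: float        # average of the class percentages

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "effect_size": self.effect_size,
            "skewness": self.skewness,
        })
        for cls in (CASE, CONTROL):
            df[f"p_{cls}"] = self.normality_p[cls]
            df[f"q_{cls}"] = self.normality_q[cls]
        return df


def _split(X: np.ndarray, y: np.ndarray) -> dict:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = {cls: X[y == cls] for cls in (CASE, CONTROL)}
    for cls, block in groups.items():
        if block.shape[0] < 2:
            raise ValueError(f"need >= 2 samples in class {cls!r}")
    return groups


def feature_effect_sizes(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|mean_case - mean_control| / pooled within-class sd, per feature.

    Features with zero pooled sd get NaN (effect undefined).
    """
    groups = _split(X, y)
    a, b = groups[CASE], groups[CONTROL]
    n1, n2 = a.shape[0], b.shape[0]
    delta = np.abs(a.mean(axis=0) - b.mean(axis=0))
    pooled_var = ((n1 - 1) * a.var(axis=0, ddof=1)
                  + (n2 - 1) * b.var(axis=0, ddof=1)) / (n1 + n2 - 2)
    sd = np.sqrt(pooled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(sd > 0, delta / sd, np.nan)
    return eff


def _population_skewness(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=0)
    centered = block - mu
    sd = np.sqrt(np.mean(centered**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        sk = np.where(sd > 0, np.mean(centered**3, axis=0) / sd**3, np.nan)
    return sk


def feature_skewness(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Average of the two within-class skewness estimates (1/n moments)."""
    groups = _split(X, y)
    for cls, block in groups.items():
        if block.shape[0] < 3:
            raise ValueError(f"skewness needs >= 3 samples in class {cls!r}")
    return (_population_skewness(groups[CASE])
            + _population_skewness(groups[CONTROL])) / 2.0


def storey_qvalues(p: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """pFDR-style q-values with the Storey pi0 estimate at one lambda."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    pi0 = min(1.0, float(np.mean(p > lambda_)) / (1.0 - lambda_))
    pi0 = max(pi0, 1.0 / m)  # guard degenerate all-small-p input
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return q


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """Multiplicity-adjusted q-values; ``method`` is 'storey' or 'bh'."""
    finite = np.isfinite(p)
    out = np.full(len(p), np.nan)
    pf = np.asarray(p, dtype=float)[finite]
    if len(pf) == 0:
        return out
    if method == "storey":
        out[finite] = storey_qvalues(pf)
    elif method == "bh":
        out[finite] = multipletests(pf, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    return out


def nongaussian_percentages(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    method: str = "storey",
) -> float:
    """Percent of features non-Gaussian within class, averaged over classes.

    A feature counts if both its Anderson-Darling p-value and its q-value
    fall below ``alpha`` in that class.
    """
    summary = summarize_features(X, y, alpha=alpha, method=method)
    return summary.percent_nongaussian


def summarize_features(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    method: str = "storey",
) -> FeatureSummary:
    groups = _split(X, y)
    for cls, block in groups.items():
        if block.shape[0] < 8:
            raise ValueError(
                f"normality testing needs >= 8 samples in class {cls!r}"
            )
    p_by_class = {}
    q_by_class = {}
    percents = []
    for cls, block in groups.items():
        pvals = np.empty(block.shape[1])
        for j in range(block.shape[1]):
            col = block[:, j]
            if np.ptp(col) == 0:
                pvals[j] = np.nan   # degenerate feature: test undefined
                continue
            pvals[j] = normal_ad(col)[1]
        qvals = qvalues(pvals, method=method)
        ok = np.isfinite(pvals)
        sig = (pvals < alpha) & (qvals < alpha) & ok
        percents.append(100.0 * sig.sum() / max(ok.sum(), 1))
        p_by_class[cls] = pvals
        q_by_class[cls] = qvals
    return FeatureSummary(
        effect_size=feature_effect_sizes(X, y),
        skewness=feature_skewness(X, y),
        normality_p=p_by_class,
        normality_q=q_by_class,
        percent_nongaussian=float(np.mean(percents)),
    )


def read_feature_table(
    path,
    sep: Optional[str] = None,
    label_column: str = "class",
    label_path=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited samples x features table (+ labels) for summarizing.

    Labels come either from ``label_column`` of the table or, if
    ``label_path`` is given, from a one-column text file of case/control
    values aligned with the rows.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if label_path is not None:
        y = pd.read_csv(label_path, header=None).iloc[:, 0].to_numpy(dtype=str)
        X = df.to_numpy(dtype=float)
    else:
        if label_column not in df.columns:
            raise ValueError(f"missing label column {label_column!r}")
        y = df[label_column].to_numpy(dtype=str)
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("label count does not match sample count")
    return X, y
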