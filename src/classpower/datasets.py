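"""Synthetic data generators for two-class biomarker discovery simulations.

Each simulated study measures ``n_features`` per subject, of which a fixed
subset (the *biomarkers*, always the leading columns) differ in mean between
cases and controls; the rest are noise.  Two generative families are
supported:

* ``gaussian`` — every feature is N(mu, sigma^2) within class, with mu = 0
  for controls and noise features and mu = delta for case biomarkers.
* ``mixture`` — each value is drawn from N(mu, sigma^2) with probability
  ``1 - tail_prob`` and from Uniform(mu + c1*sigma, mu + c2*sigma) otherwise,
  producing a right-skewed, outlier-prone distribution typical of
  log-intensity 'omics' data from human studies.  The location parameters are
  solved so that the class means are exactly 0 (control) and delta (case).

A compound-symmetric correlation among the biomarkers is supported for the
Gaussian family only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

_PURPOSE_CODES = {
    "dataset": 0,
    "null": 1,
    "alternative": 2,
    "cv": 3,
    "test": 4,
    "classifier": 5,
}


def child_seeds(root_seed: int, purpose: str, n: int) -> np.ndarray:
    """Derive ``n`` reproducible child seeds from one root seed.

    Streams are keyed by ``purpose`` so that e.g. null datasets and
    alternative datasets never share randomness, and are independent of the
    order in which they are consumed.
    """
    code = _PURPOSE_CODES[purpose]
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(code,))
    return (ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31)).astype(np.int64)


@dataclass(frozen=True)
class SimulationDesign:
    """All generator and study-size parameters for one scenario.

    ``delta`` is the per-biomarker case-minus-control mean shift on the
    measurement scale; ``delta = 0`` defines a valid null design.
    """

    n_case: int
    n_control: int
    n_features: int = 1000
    n_biomarkers: int = 10
    delta: float = 0.0
    sigma2: float = 0.2
    dist_kind: str = "gaussian"
    tail_prob: float = 0.1
    c1: float = 3.0
    c2: float = 6.7
    biomarker_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dist_kind not in ("gaussian", "mixture"):
            raise ValueError(f"unknown dist_kind {self.dist_kind!r}")
        if not (0 <= self.n_biomarkers <= self.n_features):
            raise ValueError("need 0 <= n_biomarkers <= n_features")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        for name in ("delta", "sigma2", "tail_prob", "c1", "c2",
                     "biomarker_correlation"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.c1 > self.c2:
            raise ValueError("need c1 <= c2")
        if not (0 <= self.tail_prob < 1):
            raise ValueError("need 0 <= tail_prob < 1")
        if not (0 <= self.biomarker_correlation < 1):
            raise ValueError("need 0 <= biomarker_correlation < 1")
        if self.biomarker_correlation > 0 and self.dist_kind == "mixture":
            raise ValueError(
                "correlated biomarkers are only defined for the gaussian model"
            )

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    def as_null(self) -> "SimulationDesign":
        """The matching all-noise design (delta forced to 0)."""
        return replace(self, delta=0.0)


@dataclass
class LabeledDataset:
    """Feature matrix, class labels and the true biomarker index set."""

    X: np.ndarray
    y: np.ndarray  # array of CASE/CONTROL strings
    biomarker_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be n_samples x n_features, matching y")
        labels = set(np.unique(self.y))
        if not labels <= {CASE, CONTROL}:
            raise ValueError(f"labels must be {CASE!r}/{CONTROL!r}, got {labels}")
        self.biomarker_indices = np.asarray(self.biomarker_indices, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def case_mask(self) -> np.ndarray:
        return self.y == CASE


def mixture_location_params(
    design: SimulationDesign, target_case_mean: float
) -> tuple[float, float]:
    """Location parameters (mu, mu*) of the Gaussian/uniform mixture.

    Solves E(X | control) = mu + tail_prob * sigma * (c1 + c2) / 2 = 0 for mu,
    and the analogous equation for mu* with E(X | case) = target_case_mean.
    """
    if design.dist_kind != "mixture":
        raise ValueError("location parameters are defined for the mixture model")
    tail_mean_offset = design.tail_prob * design.sigma * (design.c1 + design.c2) / 2.0
    mu = -tail_mean_offset
    mu_star = target_case_mean - tail_mean_offset
    return mu, mu_star


def mixture_moments(design: SimulationDesign) -> dict[str, float]:
    """Closed-form mean/variance/skewness of one mixture feature.

    Computed for the class with mean 0 (the moments are location-invariant,
    so they hold for both classes).  Used as the oracle for Monte-Carlo
    checks of the generator.
    """
    w = design.tail_prob
    s = design.sigma
    mu, _ = mixture_location_params(design, 0.0)
    a, b = mu + design.c1 * s, mu + design.c2 * s
    # component raw moments about 0
    m_n = np.array([mu, mu**2 + s**2, mu**3 + 3 * mu * s**2])
    mid = (a + b) / 2.0
    m_u = np.array([
        mid,
        (a**2 + a * b + b**2) / 3.0,
        (a + b) * (a**2 + b**2) / 4.0,
    ])
    m = (1 - w) * m_n + w * m_u
    mean = m[0]
    var = m[1] - mean**2
    third_central = m[2] - 3 * mean * m[1] + 2 * mean**3
    return {
        "mean": float(mean),
        "variance": float(var),
        "skewness": float(third_central / var**1.5),
    }


def effect_to_delta(effect_size: float, dist_kind: str = "gaussian") -> float:
    """Convert a labeled effect size (delta/sigma) to the mean shift delta.

    The mixture setting labels effect sizes against sd sqrt(0.8) — four times
    the Gaussian variance — matching the convention used to index the
    simulation scenarios, not the exact mixture sd.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if dist_kind == "gaussian":
        return effect_size * float(np.sqrt(0.2))
    if dist_kind == "mixture":
        return effect_size * float(np.sqrt(0.8))
    raise ValueError(f"unknown dist_kind {dist_kind!r}")


def _draw_mixture(
    rng: np.random.Generator, shape: tuple[int, ...], mu: float,
    design: SimulationDesign,
) -> np.ndarray:
    s = design.sigma
    tail = rng.random(shape) > (1.0 - design.tail_prob)
    out = rng.normal(mu, s, shape)
    n_tail = int(tail.sum())
    if n_tail:
        out[tail] = rng.uniform(mu + design.c1 * s, mu + design.c2 * s, n_tail)
    return out


def generate_dataset(design: SimulationDesign) -> LabeledDataset:
    """Draw one dataset under ``design``; deterministic given ``design.seed``.

    Cases occupy the first ``n_case`` rows; biomarkers are the first
    ``n_biomarkers`` columns.
    """
    rng = np.random.default_rng(design.seed)
    n1, n0 = design.n_case, design.n_control
    p, k = design.n_features, design.n_biomarkers
    s = design.sigma

    if design.dist_kind == "gaussian":
        X = rng.normal(0.0, s, (n1 + n0, p))
        rho = design.biomarker_correlation
        if rho > 0 and k > 1:
            corr = (1 - rho) * np.eye(k) + rho * np.ones((k, k))
            L = np.linalg.cholesky(design.sigma2 * corr)
            X[:, :k] = rng.standard_normal((n1 + n0, k)) @ L.T
        X[:n1, :k] += design.delta
    else:
        mu, mu_star = mixture_location_params(design, design.delta)
        X = _draw_mixture(rng, (n1 + n0, p), mu, design)
        if k:
            X[:n1, :k] = _draw_mixture(rng, (n1, k), mu_star, design)

    y = np.array([CASE] * n1 + [CONTROL] * n0)
    return LabeledDataset(X=X, y=y, biomarker_indices=np.arange(k))


def write_dataset(data: LabeledDataset, path, sep: str = "\t") -> None:
    """Write samples x features plus a final ``class`` column as delimited text."""
    cols = [f"feature_{j}" for j in range(data.n_features)]
    df = pd.DataFrame(data.X, columns=cols)
    df["class"] = data.y
    df.to_csv(path, sep=sep, index=False)


def read_dataset(path, sep: str = "\t", label_column: str = "class") -> LabeledDataset:
    """Read a delimited samples x features table with a class label column."""
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(f"missing label column {label_column!r}")
    y = df[label_column].to_numpy(dtype=str)
    X = df.drop(columns=[label_column]).to_numpy(dtype=float)
    return LabeledDataset(X=X, y=y)
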