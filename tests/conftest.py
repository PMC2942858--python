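import numpy as np
import pytest

from classpower import CASE, CONTROL, LabeledDataset, SimulationDesign, generate_dataset

SEED = 20260919


@pytest.fixture(scope="session")
def small_gaussian():
    """Well-powered small Gaussian dataset: 5 biomarkers among 30 features."""
    design = SimulationDesign(
        n_case=30, n_control=30, n_features=30, n_biomarkers=5,
        delta=0.6, seed=SEED,
    )
    return generate_dataset(design)


@pytest.fixture(scope="session")
def separable():
    """Two far-apart Gaussian clouds (effect size ~9)."""
    design = SimulationDesign(
        n_case=20, n_control=20, n_features=10, n_biomarkers=10,
        delta=4.0, seed=SEED + 1,
    )
    return generate_dataset(design)


@pytest.fixture(scope="session")
def noise_only():
    design = SimulationDesign(
        n_case=25, n_control=25, n_features=20, n_biomarkers=0,
        delta=0.0, seed=SEED + 2,
    )
    return generate_dataset(design)


def toy_dataset(X, y01):
    X = np.asarray(X, dtype=float)
    y = np.where(np.asarray(y01) == 1, CASE, CONTROL)
    return LabeledDataset(X=X, y=y)
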