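"""Closed-form Bayes-rule accuracy for the idealized Gaussian setting.

With two equally likely classes, p independent biomarkers of common effect
size delta/sigma and covariance sigma^2 I, the optimal (Bayes) classifier
projects onto the mean-difference direction and its probability of correct
classification is Phi((delta / (2 sigma)) * sqrt(p)).  This is the ceiling
against which simulated classifiers can be compared: no procedure that also
has to *find* the biomarkers can beat it in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class BayesSetting:
    effect_size: float        # delta / sigma per biomarker
    p_biomarkers: int
    # class prior fixed at 0.5 for both classes

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.p_biomarkers < 1:
            raise ValueError("p_biomarkers must be >= 1")


def bayes_accuracy(setting: BayesSetting) -> float:
    """Phi(effect_size / 2 * sqrt(p)), the ideal correct-classification rate."""
    return float(norm.cdf(setting.effect_size / 2.0 * np.sqrt(setting.p_biomarkers)))
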