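"""Packaged reference constants and the default synthetic-cohort settings.

``PUBLISHED_CONFUSION_COUNTS`` is the published training-set confusion matrix of the
ΔCt375 classifier (58 samples: 14 AD, 13 SQC, 8 AT, 23 TC), and
``PUBLISHED_THRESHOLDS`` the published odds cut-points {1.4, 3.0, 4.9}.  Both
are carried as constants: the per-sample training data behind them are not
public, so the cut-points are applied, never re-derived.
"""

from __future__ import annotations

import pandas as pd

from .classifier import BOXES, ThresholdSet
from .evaluation import ConfusionTable
from .simulate import CohortSpec

CLASS_A = "non-NE"   # adenocarcinoma + squamous cell carcinoma
CLASS_B = "NE"       # low-grade neuroendocrine: atypical + typical carcinoid

SUBTYPE_CLASS_MAP = {"AD": CLASS_A, "SQC": CLASS_A, "AT": CLASS_B, "TC": CLASS_B}

#: Published training-set confusion counts: subtype rows ×
#: (strong_a, weak_a, weak_b, strong_b) columns.
PUBLISHED_CONFUSION_COUNTS = {
    "AD":  {"strong_a": 9,  "weak_a": 4, "weak_b": 0,  "strong_b": 1},
    "SQC": {"strong_a": 10, "weak_a": 2, "weak_b": 1,  "strong_b": 0},
    "AT":  {"strong_a": 0,  "weak_a": 0, "weak_b": 8,  "strong_b": 0},
    "TC":  {"strong_a": 0,  "weak_a": 3, "weak_b": 15, "strong_b": 5},
}

#: Published ΔCt375 cut-points: χ10:90 = 1.4, χ = 3.0, χ90:10 = 4.9.
PUBLISHED_THRESHOLDS = ThresholdSet(chi_low=1.4, chi_mid=3.0, chi_high=4.9,
                                odds_level=9.0)


def published_confusion_table() -> ConfusionTable:
    """The published training-set confusion matrix as a ConfusionTable."""
    counts = pd.DataFrame.from_dict(PUBLISHED_CONFUSION_COUNTS, orient="index")[list(BOXES)]
    counts.index.name = "subtype"
    return ConfusionTable(counts=counts, class_map=dict(SUBTYPE_CLASS_MAP),
                          class_a=CLASS_A, class_b=CLASS_B)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A "study-like" synthetic training cohort.

    The class-conditional ΔCt375 Gaussians (non-NE: N(0.13, 2.39²),
    NE: N(5.57, 1.83²), equal priors) were obtained by solving the log-odds
    quadratic so that its −ln 9 / 0 / +ln 9 roots fall at the published
    cut-points {1.4, 3.0, 4.9}; the remaining free parameter was fixed by
    requiring the Bayes maximum accuracy to match the published ≈90.3%.
    The solved thresholds of the rounded defaults are {1.394, 2.999, 4.905}
    and their Bayes accuracy 0.9025.
    """
    spec = CohortSpec(seed=seed)
    for k, v in overrides.items():
        if not hasattr(spec, k):
            from .errors import ConfigurationError
            raise ConfigurationError(f"unknown CohortSpec field {k!r}")
        setattr(spec, k, v)
    spec.validate()
    return spec
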