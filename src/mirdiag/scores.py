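"""Normalized ΔCt expression scores as linear combinations of mean Cts.

Scores are computed on post-QC triplicate-mean Cts.  Two presets are built
in:

* ``dct375``: ΔCt375 = CtU6 − Ct375 — higher values mean more miR375-3p
  relative to the U6 normalizer (one cycle ≈ a twofold expression change);
  this is the neuroendocrine classifier score.
* ``dct205``: ΔCt205 = (Ct205 − CtU6) − 0.8·(Ct21 − CtU6), i.e. the linear
  combination {miR205: +1, miR21: −0.8, U6: −0.2} — the weighted score used
  to separate adenocarcinoma from squamous carcinoma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, MissingDataError


@dataclass(frozen=True)
class ScoreSpec:
    """A named linear combination of assay Cts: score = Σ coefficient·Ct."""

    name: str
    terms: tuple[tuple[str, float], ...]
    description: str = ""

    def __post_init__(self):
        for assay, coef in self.terms:
            if not np.isfinite(coef):
                raise ConfigurationError(
                    f"score {self.name!r}: non-finite coefficient for {assay!r}")

    @property
    def assays(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.terms)

    @classmethod
    def from_mapping(cls, name: str, terms: Mapping[str, float],
                     description: str = "") -> "ScoreSpec":
        return cls(name=name, terms=tuple(terms.items()), description=description)


DCT375 = ScoreSpec.from_mapping(
    "dct375", {"U6": 1.0, "miR375": -1.0},
    "CtU6 - Ct375: miR375-3p expression relative to the U6 normalizer")

DCT205 = ScoreSpec.from_mapping(
    "dct205", {"miR205": 1.0, "miR21": -0.8, "U6": -0.2},
    "(Ct205 - CtU6) - 0.8*(Ct21 - CtU6): weighted miR205-5p score")

PRESETS: dict[str, ScoreSpec] = {s.name: s for s in (DCT375, DCT205)}


def get_score_spec(spec: str | ScoreSpec) -> ScoreSpec:
    """Resolve a preset name or pass through a ScoreSpec."""
    if isinstance(spec, ScoreSpec):
        return spec
    try:
        return PRESETS[spec]
    except KeyError:
        raise ConfigurationError(
            f"unknown score preset {spec!r}; available: {sorted(PRESETS)}") from None


def compute_score(mean_cts: Mapping[str, float], spec: str | ScoreSpec,
                  sample_id: str = "") -> float:
    """Evaluate one score for one sample's mean Cts (exact arithmetic)."""
    spec = get_score_spec(spec)
    total = 0.0
    for assay, coef in spec.terms:
        ct = mean_cts.get(assay)
        if ct is None or not np.isfinite(ct):
            where = f" for sample {sample_id!r}" if sample_id else ""
            raise MissingDataError(
                f"score {spec.name!r}: assay {assay!r} missing{where}")
        total += coef * float(ct)
    return total


def score_table(cleaned: pd.DataFrame,
                specs: Sequence[str | ScoreSpec]) -> pd.DataFrame:
    """Compute all requested scores for every sample in a cleaned table.

    ``cleaned`` is the wide per-sample mean-Ct table produced by
    :func:`mirdiag.qc.qc_cohort`.  Output is long format, one row per
    sample per score, ordered by sample_id then score name.
    """
    if not specs:
        raise ConfigurationError("at least one score spec is required")
    specs = [get_score_spec(s) for s in specs]
    meta_cols = ("sample_id", "subtype", "class", "stage", "qc_outlier")
    frames = []
    for spec in specs:
        value = pd.Series(0.0, index=cleaned.index)
        for assay, coef in spec.terms:
            if assay not in cleaned.columns:
                raise MissingDataError(
                    f"score {spec.name!r}: assay {assay!r} missing from table")
            col = cleaned[assay].astype(float)
            bad = ~np.isfinite(col)
            if bad.any():
                sid = cleaned.loc[bad, "sample_id"].iloc[0]
                raise MissingDataError(
                    f"score {spec.name!r}: assay {assay!r} missing for sample {sid!r}")
            value = value + coef * col
        frame = pd.DataFrame({c: cleaned.get(c, "") for c in meta_cols})
        frame["qc_outlier"] = frame["qc_outlier"].astype(bool) \
            if "qc_outlier" in cleaned.columns else False
        frame["score_name"] = spec.name
        frame["value"] = value
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sample_id", "score_name"], kind="stable").reset_index(drop=True)


class CtScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer adding score columns to a mean-Ct table."""

    def __init__(self, specs: Sequence[str] | str = "dct375"):
        self.specs = specs

    def fit(self, X: pd.DataFrame, y=None) -> "CtScorer":
        names = [self.specs] if isinstance(self.specs, str) else list(self.specs)
        self.specs_ = [get_score_spec(s) for s in names]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            self.fit(X)
        out = X.copy()
        for spec in self.specs_:
            out[spec.name] = [
                compute_score({a: rec[a] for a in X.columns if a in dict(spec.terms)},
                              spec, sample_id=str(rec.get("sample_id", "")))
                for _, rec in X.iterrows()
            ]
        return out
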