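"""Evaluation surface: confusion table, accuracy/sensitivity/specificity,
ROC/AUC, class-separation t-test, stage ANOVA and normalizer stability.

The confusion table counts samples per histological subtype (rows) and per
odds box (columns).  Collapsing the four boxes to two predicted classes
(a = strong_a + weak_a, b = strong_b + weak_b) yields the overall accuracy
and the per-class rates; restricting to confident (strong) calls yields the
high-reliability accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import BOXES, BOX_CLASS, ClassCall
from .errors import InsufficientDataError, ValidationError


@dataclass
class ConfusionTable:
    """Subtype × odds-box count matrix with the subtype→class mapping."""

    counts: pd.DataFrame           # index: subtypes, columns: BOXES
    class_map: dict[str, str]      # subtype -> class label
    class_a: str                   # low-score class label
    class_b: str                   # high-score class label

    def __post_init__(self):
        missing = [b for b in BOXES if b not in self.counts.columns]
        if missing:
            raise ValidationError(f"confusion table missing box columns {missing}")
        unmapped = [s for s in self.counts.index if s not in self.class_map]
        if unmapped:
            raise ValidationError(f"subtypes without class mapping: {unmapped}")
        self.counts = self.counts[list(BOXES)].astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_sums(self) -> dict[str, int]:
        return self.counts.sum(axis=1).astype(int).to_dict()

    def collapse(self) -> pd.DataFrame:
        """Two-class predicted counts (columns 'a', 'b') per subtype."""
        out = pd.DataFrame(index=self.counts.index)
        out["a"] = self.counts["strong_a"] + self.counts["weak_a"]
        out["b"] = self.counts["strong_b"] + self.counts["weak_b"]
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("subtype").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, class_map: Mapping[str, str],
                 class_a: str, class_b: str) -> "ConfusionTable":
        counts = pd.read_csv(path, sep="\t", index_col="subtype")
        return cls(counts=counts, class_map=dict(class_map),
                   class_a=class_a, class_b=class_b)


def confusion_table(calls: Iterable[ClassCall], subtypes: Mapping[str, str],
                    class_map: Mapping[str, str], class_a: str, class_b: str,
                    subtype_order: Sequence[str] | None = None) -> ConfusionTable:
    """Count classifier calls per subtype per box."""
    calls = list(calls)
    for c in calls:
        if c.sample_id not in subtypes:
            raise ValidationError(f"sample {c.sample_id!r} has no subtype")
        if subtypes[c.sample_id] not in class_map:
            raise ValidationError(
                f"unknown subtype {subtypes[c.sample_id]!r} for sample {c.sample_id!r}")
    order = list(subtype_order) if subtype_order else \
        sorted({subtypes[c.sample_id] for c in calls})
    counts = pd.DataFrame(0, index=pd.Index(order, name="subtype"),
                          columns=list(BOXES), dtype=int)
    for c in calls:
        counts.loc[subtypes[c.sample_id], c.box] += 1
    return ConfusionTable(counts=counts, class_map=dict(class_map),
                          class_a=class_a, class_b=class_b)


@dataclass
class MetricsReport:
    """Classification metrics on the percent scale (full precision kept).

    ``rate_class_a``/``rate_class_b`` are the per-class correct-call rates;
    for the ΔCt375 classifier these correspond to the reported sensitivity
    (non-NE) and specificity (NE).
    """

    accuracy_all: float
    rate_class_a: float
    rate_class_b: float
    accuracy_high_reliability: float
    n_high_reliability: int
    n_total: int
    auc: float | None = None
    t_statistic: float | None = None
    t_pvalue: float | None = None
    anova: dict | None = None
    normalizer: dict | None = None

    # conventional diagnostic aliases
    @property
    def sensitivity(self) -> float:
        return self.rate_class_a

    @property
    def specificity(self) -> float:
        return self.rate_class_b

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")


def classification_metrics(table: ConfusionTable) -> MetricsReport:
    """Accuracy and per-class rates from a subtype × box confusion table."""
    if table.total == 0:
        raise InsufficientDataError("empty confusion table")
    two = table.collapse()
    true_class = pd.Series({s: table.class_map[s] for s in table.counts.index})
    is_a = true_class == table.class_a

    correct = int(two.loc[is_a, "a"].sum() + two.loc[~is_a, "b"].sum())
    n_a = int(two.loc[is_a].to_numpy().sum())
    n_b = int(two.loc[~is_a].to_numpy().sum())
    rate_a = 100.0 * two.loc[is_a, "a"].sum() / n_a if n_a else math.nan
    rate_b = 100.0 * two.loc[~is_a, "b"].sum() / n_b if n_b else math.nan

    strong = table.counts[["strong_a", "strong_b"]]
    n_strong = int(strong.to_numpy().sum())
    correct_strong = int(strong.loc[is_a, "strong_a"].sum()
                         + strong.loc[~is_a, "strong_b"].sum())
    acc_hr = 100.0 * correct_strong / n_strong if n_strong else math.nan

    return MetricsReport(
        accuracy_all=100.0 * correct / table.total,
        rate_class_a=float(rate_a), rate_class_b=float(rate_b),
        accuracy_high_reliability=float(acc_hr),
        n_high_reliability=n_strong, n_total=table.total)


def empirical_roc_auc(scores: Sequence[float], labels: Sequence,
                      pos_label) -> tuple[pd.DataFrame, float]:
    """Empirical ROC points and AUC (Mann–Whitney; ties count one half).

    ``pos_label`` is the high-score (positive) class.  Points include
    (0, 0) and (1, 1).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == pos_label
    if pos.all() or not pos.any():
        raise InsufficientDataError("both classes must be present for ROC")
    fpr, tpr, thr = roc_curve(pos.astype(int), x, pos_label=1)
    auc = float(roc_auc_score(pos.astype(int), x))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc


def separation_t_test(scores: Sequence[float], labels: Sequence,
                      equal_var: bool = True) -> tuple[float, float]:
    """Two-sample Student's t between the two classes (Welch optional)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InsufficientDataError(f"need exactly 2 classes, got {len(classes)}")
    g0, g1 = x[y == classes[0]], x[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise InsufficientDataError("need >= 2 samples per class for a t-test")
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        if g0.mean() == g1.mean():
            return 0.0, 1.0
        raise InsufficientDataError("zero variance in both groups")
    t, p = stats.ttest_ind(g0, g1, equal_var=equal_var)
    return float(t), float(p)


def stage_anova(scores: Sequence[float], stages: Sequence,
                min_group_size: int = 2) -> tuple[float, float]:
    """One-way ANOVA of scores across clinical-stage groups."""
    x = np.asarray(scores, dtype=float)
    s = np.asarray(stages)
    groups = []
    for stage in pd.unique(s):
        if stage is None or stage == "" or (isinstance(stage, float) and math.isnan(stage)):
            continue
        g = x[s == stage]
        if len(g) >= min_group_size:
            groups.append(g)
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 stage groups with >= {min_group_size} samples")
    if all(g.std(ddof=1) == 0 for g in groups) and \
            len({float(g.mean()) for g in groups}) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class NormalizerReport:
    """Stability check of the endogenous normalizer across classes."""

    mean_a: float
    mean_b: float
    delta_mean: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    stable: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def normalizer_stability(u6_means: Sequence[float], labels: Sequence,
                         class_a: str, class_b: str,
                         delta_threshold: float = 1.0,
                         alpha: float = 0.05) -> NormalizerReport:
    """Compare normalizer Ct between classes.

    Flagged unstable only if the difference is both statistically detectable
    (p < alpha) and practically large (|Δmean| > delta_threshold cycles) —
    a tiny but significant shift does not disqualify a normalizer.
    """
    x = np.asarray(u6_means, dtype=float)
    y = np.asarray(labels)
    ga, gb = x[y == class_a], x[y == class_b]
    if len(ga) < 2 or len(gb) < 2:
        raise InsufficientDataError("need >= 2 samples per class")
    t, p = separation_t_test(x[(y == class_a) | (y == class_b)],
                             y[(y == class_a) | (y == class_b)])
    delta = float(gb.mean() - ga.mean())
    return NormalizerReport(
        mean_a=float(ga.mean()), mean_b=float(gb.mean()), delta_mean=delta,
        sd_a=float(ga.std(ddof=1)), sd_b=float(gb.std(ddof=1)),
        t_statistic=t, p_value=p,
        stable=not (p < alpha and abs(delta) > delta_threshold))
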