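"""Technical-outlier identification on Ct triplicates.

Every RT-qPCR measurement arrives as a technical triplicate.  A triplicate
is screened in two stages before its mean Ct enters any downstream score:

1. **Variability** — the within-triplicate variance is compared to the
   pooled technical variance of the assay with a chi-square test:
   (n−1)s²/σ₀² against the upper χ²(n−1) quantile.  A triplicate that fails
   may have its most deviant replicate (farthest from the triplicate
   median) removed once; the surviving pair is re-tested.
2. **Deviation** — the (surviving) triplicate mean is compared to the
   population of triplicate means for the same assay with a two-sided
   Student's t-test; a mean that is significantly displaced flags the
   whole measurement as a technical outlier.

A triplicate passes only if both stages pass.  The pooled reference SD σ₀
is estimated per assay from all triplicates, after excluding the most
variable 10% so that the very outliers under test do not inflate the
reference variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InsufficientDataError, ValidationError

PASS = "pass"
PASS_AFTER_REMOVAL = "pass_after_removal"
OUTLIER = "outlier"


@dataclass
class QCParams:
    """Significance levels and removal policy for triplicate QC.

    alpha_var : chi-square variability test level (two of three replicates
        agreeing tightly is the norm; 0.05 default).
    alpha_mean : deviation (t) test level.
    min_replicates : never reduce a triplicate below this many replicates.
    max_removals : at most this many replicates may be discarded.
    trim_fraction : fraction of the most-variable triplicates excluded when
        pooling the reference variance (0 disables).
    per_class_population : compute the deviation-test population per class
        instead of over all samples (class labels are unknown at QC time in
        classify-only mode, hence False by default).
    """

    alpha_var: float = 0.05
    alpha_mean: float = 0.05
    min_replicates: int = 2
    max_removals: int = 1
    trim_fraction: float = 0.10
    per_class_population: bool = False

    def validate(self) -> None:
        from .errors import ConfigurationError
        if not 0 < self.alpha_var < 1:
            raise ConfigurationError(f"alpha_var must be in (0,1), got {self.alpha_var}")
        if not 0 < self.alpha_mean < 1:
            raise ConfigurationError(f"alpha_mean must be in (0,1), got {self.alpha_mean}")
        if self.min_replicates < 2:
            raise ConfigurationError("min_replicates must be >= 2")
        if not 0 <= self.trim_fraction < 1:
            raise ConfigurationError("trim_fraction must be in [0,1)")


@dataclass
class PooledNoiseEstimate:
    """Pooled within-triplicate SD for one assay (the χ² reference σ₀)."""

    assay: str
    sigma0: float
    dof: int
    n_triplicates: int


@dataclass
class QCVerdict:
    """Outcome of the two QC tests for one sample × assay triplicate."""

    sample_id: str = ""
    assay: str = ""
    status: str = PASS
    removed_replicates: list[int] = field(default_factory=list)
    triplicate_mean: float = math.nan
    triplicate_sd: float = math.nan
    var_statistic: float = math.nan
    var_pvalue: float = math.nan
    mean_statistic: float = math.nan
    mean_pvalue: float = math.nan
    reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_pooled_sd(table: pd.DataFrame, assay: str,
                       trim_fraction: float = 0.10) -> PooledNoiseEstimate:
    """Pool within-triplicate variances of one assay: σ₀² = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1).

    The ``trim_fraction`` most variable triplicates are excluded from the
    pool so gross outliers do not set their own reference.
    """
    sub = table.loc[(table["assay"] == assay) & np.isfinite(table["ct"]),
                    ["sample_id", "ct"]]
    g = sub.groupby("sample_id", sort=False)["ct"]
    sizes, variances = g.count().to_numpy(), g.var(ddof=1).to_numpy()
    keep_mask = sizes >= 2
    groups = list(zip(sizes[keep_mask].tolist(), variances[keep_mask].tolist()))
    if len(groups) < 2:
        raise InsufficientDataError(
            f"assay {assay!r}: need >= 2 triplicates with >= 2 replicates to pool variance")
    groups.sort(key=lambda t: t[1])
    k = int(len(groups) * trim_fraction)
    kept = groups[: len(groups) - k] if k > 0 else groups
    dof = sum(n - 1 for n, _ in kept)
    sigma0_sq = sum((n - 1) * v for n, v in kept) / dof
    return PooledNoiseEstimate(assay=assay, sigma0=math.sqrt(sigma0_sq),
                               dof=dof, n_triplicates=len(kept))


def _farthest_from_median(cts: np.ndarray) -> int:
    """Index of the replicate farthest from the median (ties: the larger value)."""
    med = np.median(cts)
    dist = np.abs(cts - med)
    far = np.flatnonzero(dist == dist.max())
    return int(far[np.argmax(cts[far])])


def assess_triplicate(
    cts: Sequence[float],
    sigma0: PooledNoiseEstimate | float,
    pop_mean: float,
    pop_sd: float,
    params: QCParams | None = None,
    pop_dof: int | None = None,
) -> QCVerdict:
    """Run the variability and deviation tests on one Ct triplicate.

    NaN replicates count as missing and are dropped; infinite values are a
    validation error.  Fewer than two finite replicates yields an outlier
    verdict with reason "insufficient replicates".  The verdict records the
    final statistics (after any replicate removal); a verdict passes only
    if both tests pass.
    """
    params = params or QCParams()
    params.validate()
    s0 = sigma0.sigma0 if isinstance(sigma0, PooledNoiseEstimate) else float(sigma0)
    original = np.asarray(list(cts), dtype=float)
    if np.any(np.isinf(original)):
        raise ValidationError("infinite Ct value in triplicate")
    idx = np.flatnonzero(np.isfinite(original))
    arr = original[idx]
    if len(arr) < 2:
        return QCVerdict(status=OUTLIER, reason="insufficient replicates",
                         triplicate_mean=float(arr.mean()) if len(arr) else math.nan)

    removed: list[int] = []
    removals_left = params.max_removals

    # --- variability (chi-square) stage ---
    var_stat = var_p = math.nan
    if s0 > 0:
        while True:
            n = len(arr)
            s2 = float(np.var(arr, ddof=1))
            var_stat = (n - 1) * s2 / (s0 * s0)
            var_p = float(special.chdtrc(n - 1, var_stat))
            if var_p >= params.alpha_var:
                break
            if removals_left > 0 and n - 1 >= params.min_replicates:
                j = _farthest_from_median(arr)
                removed.append(int(idx[j]))
                arr = np.delete(arr, j)
                idx = np.delete(idx, j)
                removals_left -= 1
            else:
                return QCVerdict(status=OUTLIER, removed_replicates=removed,
                                 triplicate_mean=float(arr.mean()),
                                 triplicate_sd=float(np.std(arr, ddof=1)),
                                 var_statistic=var_stat, var_pvalue=var_p,
                                 reason="excess within-triplicate variability")
    else:
        var_stat, var_p = 0.0, 1.0  # reference variance zero: test skipped

    mean = float(arr.mean())
    sd = float(np.std(arr, ddof=1))

    # --- deviation (Student's t) stage ---
    mean_stat = mean_p = math.nan
    if pop_sd is not None and pop_sd > 0:
        mean_stat = (mean - pop_mean) / pop_sd
        if pop_dof is not None and pop_dof > 0:
            mean_p = 2.0 * float(special.stdtr(pop_dof, -abs(mean_stat)))
        else:
            mean_p = 2.0 * float(special.ndtr(-abs(mean_stat)))
        if mean_p < params.alpha_mean:
            return QCVerdict(status=OUTLIER, removed_replicates=removed,
                             triplicate_mean=mean, triplicate_sd=sd,
                             var_statistic=var_stat, var_pvalue=var_p,
                             mean_statistic=mean_stat, mean_pvalue=mean_p,
                             reason="mean deviates from assay population")

    status = PASS_AFTER_REMOVAL if removed else PASS
    return QCVerdict(status=status, removed_replicates=removed,
                     triplicate_mean=mean, triplicate_sd=sd,
                     var_statistic=var_stat, var_pvalue=var_p,
                     mean_statistic=mean_stat, mean_pvalue=mean_p)


class TriplicateQC(TransformerMixin, BaseEstimator):
    """Triplicate quality control as an sklearn-style transformer.

    ``fit`` learns, per assay, the pooled technical SD (χ² reference) and
    the population mean/SD of triplicate means (t-test reference) from a
    raw Ct table.  ``transform`` assesses every triplicate of a (possibly
    different) table against those references and returns one row per
    surviving sample with its post-QC mean Ct per assay.  Verdicts for the
    last transformed table are kept in ``verdicts_``.

    Parameters mirror :class:`QCParams`; ``required_assays`` lists the
    assays a sample must pass to stay in the cleaned table (default: every
    assay seen at fit time), and ``keep_outliers`` retains flagged samples
    in the output with ``qc_outlier=True`` so they can still be scored and
    plotted.
    """

    def __init__(self, alpha_var: float = 0.05, alpha_mean: float = 0.05,
                 min_replicates: int = 2, max_removals: int = 1,
                 trim_fraction: float = 0.10,
                 required_assays: Sequence[str] | None = None,
                 keep_outliers: bool = False):
        self.alpha_var = alpha_var
        self.alpha_mean = alpha_mean
        self.min_replicates = min_replicates
        self.max_removals = max_removals
        self.trim_fraction = trim_fraction
        self.required_assays = required_assays
        self.keep_outliers = keep_outliers

    def _params(self) -> QCParams:
        p = QCParams(alpha_var=self.alpha_var, alpha_mean=self.alpha_mean,
                     min_replicates=self.min_replicates,
                     max_removals=self.max_removals,
                     trim_fraction=self.trim_fraction)
        p.validate()
        return p

    def fit(self, X: pd.DataFrame, y=None) -> "TriplicateQC":
        params = self._params()
        if len(X) == 0:
            raise InsufficientDataError("empty Ct table")
        assays = list(X["assay"].unique())
        self.pooled_sd_: dict[str, PooledNoiseEstimate] = {}
        self.population_: dict[str, tuple[float, float, int]] = {}
        for assay in assays:
            self.pooled_sd_[assay] = estimate_pooled_sd(X, assay, params.trim_fraction)
            means = (X[X["assay"] == assay]
                     .groupby("sample_id", sort=False)["ct"].mean().to_numpy())
            if len(means) >= 2:
                self.population_[assay] = (float(means.mean()),
                                           float(means.std(ddof=1)),
                                           len(means) - 1)
            else:
                self.population_[assay] = (float(means.mean()), 0.0, 0)
        self.assays_ = assays
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pooled_sd_"):
            raise InsufficientDataError("TriplicateQC must be fitted before transform")
        params = self._params()
        required = list(self.required_assays) if self.required_assays else self.assays_

        verdicts: list[QCVerdict] = []
        sample_meta: dict[str, dict] = {}
        means: dict[str, dict[str, float]] = {}
        flagged: dict[str, bool] = {}

        # collect each triplicate's Cts (replicate order) without repeated
        # DataFrame slicing; preserves first-appearance sample order
        ordered = X.sort_values("replicate", kind="stable")
        triplicates: dict[str, dict[str, list[float]]] = {}
        has_meta = [c for c in ("subtype", "class", "stage") if c in X.columns]
        meta_rows = X.drop_duplicates("sample_id").set_index("sample_id")
        for sid, assay, ct in zip(ordered["sample_id"].to_numpy(),
                                  ordered["assay"].to_numpy(),
                                  ordered["ct"].to_numpy()):
            triplicates.setdefault(sid, {}).setdefault(assay, []).append(float(ct))
        for sid in X["sample_id"].drop_duplicates():
            meta = meta_rows.loc[sid]
            sample_meta[sid] = {c: meta[c] if c in has_meta else ""
                                for c in ("subtype", "class", "stage")}
            means[sid] = {}
            flagged[sid] = False
            present = triplicates.get(sid, {})
            for assay in self.assays_:
                if assay not in present:
                    if assay in required:
                        verdicts.append(QCVerdict(sample_id=sid, assay=assay,
                                                  status=OUTLIER, reason="missing assay"))
                        flagged[sid] = True
                    continue
                pm, ps, pdof = self.population_[assay]
                v = assess_triplicate(present[assay], self.pooled_sd_[assay],
                                      pm, ps, params, pop_dof=pdof)
                v.sample_id, v.assay = sid, assay
                verdicts.append(v)
                if v.status == OUTLIER and assay in required:
                    flagged[sid] = True
                if np.isfinite(v.triplicate_mean):
                    means[sid][assay] = v.triplicate_mean

        rows = []
        for sample_id, meta in sample_meta.items():
            if flagged[sample_id] and not self.keep_outliers:
                continue
            row = {"sample_id": sample_id, **meta, "qc_outlier": flagged[sample_id]}
            row.update(means[sample_id])
            rows.append(row)
        cols = ["sample_id", "subtype", "class", "stage", "qc_outlier"] + self.assays_
        cleaned = pd.DataFrame(rows, columns=cols)
        self.verdicts_ = verdicts
        return cleaned


def qc_cohort(table: pd.DataFrame, params: QCParams | None = None,
              required_assays: Sequence[str] | None = None,
              keep_outliers: bool = False) -> tuple[pd.DataFrame, list[QCVerdict]]:
    """QC an entire cohort: pooled SDs per assay, verdict per triplicate.

    Returns the cleaned table of per-sample per-assay mean Cts (samples
    whose required assays were flagged are excluded unless
    ``keep_outliers``) and the exhaustive verdict list.
    """
    params = params or QCParams()
    qc = TriplicateQC(alpha_var=params.alpha_var, alpha_mean=params.alpha_mean,
                      min_replicates=params.min_replicates,
                      max_removals=params.max_removals,
                      trim_fraction=params.trim_fraction,
                      required_assays=required_assays,
                      keep_outliers=keep_outliers)
    cleaned = qc.fit(table).transform(table)
    return cleaned, qc.verdicts_


def verdicts_to_frame(verdicts: Iterable[QCVerdict]) -> pd.DataFrame:
    """Flatten verdicts into a report table (one row per sample × assay)."""
    rows = []
    for v in verdicts:
        d = v.to_dict()
        d["removed_replicates"] = ";".join(str(i + 1) for i in v.removed_replicates)
        rows.append(d)
    return pd.DataFrame(rows)
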