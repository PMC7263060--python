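"""Two-class Bayesian classifier on a scalar ΔCt score.

The model assumes the score's class-conditional distributions are Gaussian
(triplicate-mean Cts are close to normal), so the classifier is fully
described by per-class (μ, σ) and class priors.  The posterior odds of the
high-score class b against the low-score class a at score x are

    odds(b:a | x) = prior_b · φ(x; μ_b, σ_b) / (prior_a · φ(x; μ_a, σ_a)),

whose logarithm is quadratic in x (linear when σ_a = σ_b).  Three score
cut-points partition the axis into four decision boxes:

* χ10:90 — odds 1:L below this is a confident class-a call,
* χ      — odds 1:1, the two-class decision boundary,
* χ90:10 — odds L:1 above this is a confident class-b call,

with L the odds level (default 9, i.e. 90:10).  The attainable ceiling of
any decision rule, the Bayes maximum accuracy ∫ max(prior·φ) dx, is
computed piecewise-analytically from Gaussian CDFs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, column_or_1d

from .errors import (ConfigurationError, DegenerateModelError,
                     InsufficientDataError, ThresholdSolveError, ValidationError)

BOXES = ("strong_a", "weak_a", "weak_b", "strong_b")

#: box -> predicted binary class side
BOX_CLASS = {"strong_a": "a", "weak_a": "a", "weak_b": "b", "strong_b": "b"}


@dataclass
class GaussianClassModel:
    """Per-class Gaussian parameters and priors for a scalar score.

    Class a is the low-score class (non-NE for ΔCt375), class b the
    high-score class (low-grade NE).
    """

    class_a: str
    class_b: str
    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    prior_a: float = 0.5
    prior_b: float = 0.5
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self):
        if self.sigma_a <= 0 or self.sigma_b <= 0:
            raise DegenerateModelError(
                f"class SDs must be positive (sigma_a={self.sigma_a}, "
                f"sigma_b={self.sigma_b})")
        if not (0 < self.prior_a < 1 and 0 < self.prior_b < 1
                and abs(self.prior_a + self.prior_b - 1.0) < 1e-9):
            raise ConfigurationError(
                f"priors must lie in (0,1) and sum to 1, got "
                f"({self.prior_a}, {self.prior_b})")
        if self.mu_b <= self.mu_a:
            warnings.warn(
                f"class {self.class_b!r} mean ({self.mu_b}) is not above class "
                f"{self.class_a!r} mean ({self.mu_a}); score orientation may be flipped",
                stacklevel=2)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaussianClassModel":
        return cls(**dict(d))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianClassModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ThresholdSet:
    """The three odds cut-points: χ10:90 ≤ χ ≤ χ90:10 (score units)."""

    chi_low: float
    chi_mid: float
    chi_high: float
    odds_level: float = 9.0

    def __post_init__(self):
        if not (self.chi_low <= self.chi_mid <= self.chi_high):
            raise ValidationError(
                f"thresholds must be ordered: got ({self.chi_low}, "
                f"{self.chi_mid}, {self.chi_high})")
        if self.odds_level <= 1:
            raise ConfigurationError(f"odds_level must be > 1, got {self.odds_level}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.chi_low, self.chi_mid, self.chi_high)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdSet":
        return cls(**dict(d))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_string(cls, text: str, odds_level: float = 9.0) -> "ThresholdSet":
        parts = [float(p) for p in text.replace(";", ",").split(",") if p.strip()]
        if len(parts) != 3:
            raise ConfigurationError(
                f"expected three comma-separated thresholds, got {text!r}")
        return cls(*sorted(parts), odds_level=odds_level)


@dataclass
class ClassCall:
    """Classifier output for one sample."""

    sample_id: str
    score: float
    box: str
    predicted_class: str
    posterior_b: float = math.nan
    odds_b_over_a: float = math.nan
    qc_outlier: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resolve_priors(priors, n_a: int, n_b: int) -> tuple[float, float]:
    if priors is None or priors == "equal":
        return 0.5, 0.5
    if priors == "empirical":
        total = n_a + n_b
        return n_a / total, n_b / total
    pa, pb = float(priors[0]), float(priors[1])
    return pa, pb


def fit_model(scores: Sequence[float], labels: Sequence,
              priors="equal") -> GaussianClassModel:
    """Fit per-class Gaussians to scalar scores.

    μ is the sample mean, σ the ddof=1 sample SD per class; orientation is
    auto-detected (the higher-mean class becomes class b).  ``priors`` is
    "equal" (default), "empirical" (class frequencies) or a (prior_a,
    prior_b) pair.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite score values in training data")
    classes = np.unique(y)
    if len(classes) != 2:
        raise InsufficientDataError(
            f"exactly 2 classes required, got {len(classes)}: {list(classes)}")
    stats_by_class = {}
    for c in classes:
        xc = x[y == c]
        if len(xc) < 2:
            raise InsufficientDataError(
                f"class {c!r} has {len(xc)} samples; need >= 2")
        sd = float(xc.std(ddof=1))
        if sd == 0.0:
            raise DegenerateModelError(f"class {c!r} has zero score variance")
        stats_by_class[c] = (float(xc.mean()), sd, len(xc))
    # orientation: class b = higher mean
    c0, c1 = classes
    if stats_by_class[c0][0] <= stats_by_class[c1][0]:
        cls_a, cls_b = c0, c1
    else:
        cls_a, cls_b = c1, c0
    mu_a, sigma_a, n_a = stats_by_class[cls_a]
    mu_b, sigma_b, n_b = stats_by_class[cls_b]
    prior_a, prior_b = _resolve_priors(priors, n_a, n_b)
    return GaussianClassModel(class_a=str(cls_a), class_b=str(cls_b),
                              mu_a=mu_a, sigma_a=sigma_a,
                              mu_b=mu_b, sigma_b=sigma_b,
                              prior_a=prior_a, prior_b=prior_b,
                              n_a=n_a, n_b=n_b)


def _logodds_coefficients(model: GaussianClassModel,
                          include_priors: bool = True) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of log-odds(b:a)(x) = A·x² + B·x + C."""
    sa2, sb2 = model.sigma_a ** 2, model.sigma_b ** 2
    A = 0.5 / sa2 - 0.5 / sb2
    B = model.mu_b / sb2 - model.mu_a / sa2
    C = (math.log(model.sigma_a / model.sigma_b)
         + model.mu_a ** 2 / (2 * sa2) - model.mu_b ** 2 / (2 * sb2))
    if include_priors:
        C += math.log(model.prior_b / model.prior_a)
    return A, B, C


def log_posterior_odds(model: GaussianClassModel, x,
                       include_priors: bool = True):
    """Log posterior odds of class b against class a at score(s) x."""
    xa = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xa)):
        raise ValidationError("score must be finite to evaluate posterior odds")
    A, B, C = _logodds_coefficients(model, include_priors)
    out = A * xa ** 2 + B * xa + C
    return float(out) if np.isscalar(x) else out


def posterior_odds(model: GaussianClassModel, x, include_priors: bool = True):
    """Posterior odds (natural scale) of class b against class a."""
    return np.exp(log_posterior_odds(model, x, include_priors))


def solve_thresholds(model: GaussianClassModel, odds_level: float = 9.0,
                     include_priors: bool = True,
                     tol: float = 1e-9) -> ThresholdSet:
    """Solve the three cut-points where log-odds equals −ln L, 0, +ln L.

    With equal class variances the log-odds is linear and solved in closed
    form.  Otherwise it is quadratic: the 1:1 root lying between the class
    means becomes χ, and χ10:90/χ90:10 are taken on the same monotone branch
    (the same side of the parabola's vertex) so the three thresholds realise
    the single-cut geometry of a scalar classifier.
    """
    if odds_level <= 1:
        raise ConfigurationError(f"odds_level must be > 1, got {odds_level}")
    lnL = math.log(odds_level)
    A, B, C = _logodds_coefficients(model, include_priors)
    targets = (-lnL, 0.0, lnL)

    scale = max(abs(B), abs(A) * max(abs(model.mu_a), abs(model.mu_b), 1.0))
    if abs(A) < 1e-12 * max(scale, 1.0):
        if B == 0:
            raise ThresholdSolveError("log-odds is constant; classes indistinguishable")
        xs = [(t - C) / B for t in targets]
    else:
        lo_m, hi_m = sorted((model.mu_a, model.mu_b))
        # chi (1:1 boundary): the root between the class means
        roots_mid = _quad_roots(A, B, C - 0.0)
        in_between = [r for r in roots_mid if lo_m - tol <= r <= hi_m + tol]
        if in_between:
            chi_mid = min(in_between, key=lambda r: abs(r - 0.5 * (lo_m + hi_m)))
        else:
            chi_mid = min(roots_mid, key=lambda r: abs(r - 0.5 * (lo_m + hi_m)))
        vertex = -B / (2 * A)
        side = 1.0 if chi_mid >= vertex else -1.0

        def branch_root(t: float) -> float:
            roots = _quad_roots(A, B, C - t)
            same_side = [r for r in roots if side * (r - vertex) >= -tol]
            if not same_side:
                disc = B * B - 4 * A * (C - t)
                raise ThresholdSolveError(
                    f"no root at log-odds {t:.4f} on the admissible branch "
                    f"(discriminant={disc:.4g})")
            return min(same_side, key=lambda r: abs(r - chi_mid))

        xs = [branch_root(targets[0]), chi_mid, branch_root(targets[2])]

    for x, t in zip(xs, targets):
        err = abs(log_posterior_odds(model, x, include_priors) - t)
        if err > 1e-9 * max(1.0, abs(t)) + 1e-9:
            raise ThresholdSolveError(
                f"threshold verification failed at target {t:.4f}: residual {err:.2e}")
    lo, mid, hi = sorted(xs)
    return ThresholdSet(chi_low=lo, chi_mid=mid, chi_high=hi, odds_level=odds_level)


def _quad_roots(a: float, b: float, c: float) -> list[float]:
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ThresholdSolveError(
            f"log-odds quadratic has no real root (discriminant={disc:.4g})")
    r = math.sqrt(disc)
    # numerically stable quadratic formula
    q = -0.5 * (b + math.copysign(r, b))
    roots = {q / a if a != 0 else math.nan, c / q if q != 0 else -b / (2 * a)}
    return sorted(x for x in roots if math.isfinite(x))


def assign_box(x: float, thresholds: ThresholdSet) -> str:
    """Four-box assignment; values exactly at a cut fall in the lower box."""
    if x > thresholds.chi_high:
        return "strong_b"
    if x > thresholds.chi_mid:
        return "weak_b"
    if x > thresholds.chi_low:
        return "weak_a"
    return "strong_a"


def classify_sample(x: float, thresholds: ThresholdSet,
                    model: GaussianClassModel | None = None,
                    sample_id: str = "", qc_outlier: bool = False) -> ClassCall:
    """Assign one score to its odds box; posteriors filled if a model is given."""
    if not np.isfinite(x):
        raise ValidationError(f"score for sample {sample_id!r} is not finite: {x}")
    box = assign_box(float(x), thresholds)
    post = odds = math.nan
    if model is not None:
        lo = log_posterior_odds(model, float(x))
        odds = math.exp(lo)
        post = odds / (1.0 + odds) if math.isfinite(odds) else 1.0
    side = BOX_CLASS[box]
    pred = (model.class_a if model else "a") if side == "a" else \
        (model.class_b if model else "b")
    return ClassCall(sample_id=sample_id, score=float(x), box=box,
                     predicted_class=str(pred), posterior_b=post,
                     odds_b_over_a=odds, qc_outlier=qc_outlier)


def bayes_max_accuracy(model: GaussianClassModel) -> float:
    """Best accuracy attainable by any decision rule: ∫ max(prior·φ) dx.

    Computed piecewise-analytically: the density-ratio crossing points are
    the real roots of the log-odds quadratic; between consecutive crossings
    the dominating class's prior-weighted mass is accumulated via Φ.
    """
    A, B, C = _logodds_coefficients(model)
    if abs(A) < 1e-300 and abs(B) < 1e-300:
        # proportional densities: no rule beats the larger prior
        return max(model.prior_a, model.prior_b)
    try:
        if abs(A) < 1e-15:
            roots = [(0.0 - C) / B]
        else:
            roots = _quad_roots(A, B, C)
    except ThresholdSolveError:
        roots = []
    edges = [-math.inf] + sorted(roots) + [math.inf]
    width = 10 * max(model.sigma_a, model.sigma_b) + abs(model.mu_b - model.mu_a)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == -math.inf:
            probe = (hi if math.isfinite(hi) else model.mu_a) - width
        elif hi == math.inf:
            probe = lo + width
        else:
            probe = 0.5 * (lo + hi)
        dominant_b = log_posterior_odds(model, probe) > 0
        mu = model.mu_b if dominant_b else model.mu_a
        sd = model.sigma_b if dominant_b else model.sigma_a
        prior = model.prior_b if dominant_b else model.prior_a
        z_lo = (lo - mu) / sd if math.isfinite(lo) else -math.inf
        z_hi = (hi - mu) / sd if math.isfinite(hi) else math.inf
        total += prior * (norm.cdf(z_hi) - norm.cdf(z_lo))
    return float(total)


class GaussianBayesClassifier(ClassifierMixin, BaseEstimator):
    """Scalar Gaussian Bayes classifier with posterior-odds decision boxes.

    Fits per-class Gaussians to a one-dimensional score, solves the three
    odds cut-points, and predicts via the 1:1 boundary χ.  Scikit-learn
    compatible: X is (n, 1) or (n,), y the two class labels.

    Parameters
    ----------
    priors : "equal" (default), "empirical", or (prior_a, prior_b).
    odds_level : odds defining the confident boxes (default 9 → 90:10).
    thresholds : optional (low, mid, high) override; when given, fitted
        thresholds are replaced by these fixed cut-points (used to apply
        previously published cut-points without refitting their model).

    Attributes
    ----------
    classes_ : ndarray of the two labels (sorted, sklearn convention).
    model_ : the fitted :class:`GaussianClassModel`.
    thresholds_ : the :class:`ThresholdSet` in force.
    """

    def __init__(self, priors="equal", odds_level: float = 9.0,
                 thresholds: tuple[float, float, float] | None = None):
        self.priors = priors
        self.odds_level = odds_level
        self.thresholds = thresholds

    @staticmethod
    def _scores(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValidationError(
                    f"the classifier takes a single score column, got shape {x.shape}")
            x = x[:, 0]
        return column_or_1d(x)

    def fit(self, X, y) -> "GaussianBayesClassifier":
        x = self._scores(X)
        y = column_or_1d(np.asarray(y))
        if len(x) != len(y):
            raise ValidationError("X and y have different lengths")
        self.model_ = fit_model(x, y, priors=self.priors)
        self.classes_ = np.unique(y)
        if self.thresholds is not None:
            self.thresholds_ = (self.thresholds
                                if isinstance(self.thresholds, ThresholdSet)
                                else ThresholdSet(*self.thresholds,
                                                  odds_level=self.odds_level))
        else:
            self.thresholds_ = solve_thresholds(self.model_, self.odds_level)
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return np.asarray(log_posterior_odds(self.model_, self._scores(X)))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        x = self._scores(X)
        b = x > self.thresholds_.chi_mid
        return np.where(b, self.model_.class_b, self.model_.class_a)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        lo = self.decision_function(X)
        pb = 1.0 / (1.0 + np.exp(-lo))
        cols = {self.model_.class_a: 1.0 - pb, self.model_.class_b: pb}
        return np.column_stack([cols[str(c)] for c in self.classes_])

    def predict_box(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return np.array([assign_box(v, self.thresholds_) for v in self._scores(X)])

    def bayes_max_accuracy(self) -> float:
        check_is_fitted(self, "model_")
        return bayes_max_accuracy(self.model_)
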