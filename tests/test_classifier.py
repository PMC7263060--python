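import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import clone

from mirdiag.classifier import (GaussianBayesClassifier, GaussianClassModel,
                                ThresholdSet, assign_box, bayes_max_accuracy,
                                classify_sample, fit_model, log_posterior_odds,
                                posterior_odds, solve_thresholds)
from mirdiag.errors import (DegenerateModelError, InsufficientDataError,
                            ThresholdSolveError, ValidationError)
from mirdiag.fixtures import PUBLISHED_THRESHOLDS

LN9 = math.log(9.0)


def symmetric_model(d=4.0):
    return GaussianClassModel("a", "b", 0.0, 1.0, d, 1.0)


class TestFitModel:
    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fit_model([1.0, 1.0, 5.0, 5.0], ["a", "a", "b", "b"])

    def test_single_sample_class_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_model([1.0, 2.0, 5.0], ["a", "a", "b"])

    def test_hand_computed_moments(self):
        m = fit_model([0.0, 2.0, 4.0, 6.0], ["a", "a", "b", "b"])
        assert (m.mu_a, m.mu_b) == (1.0, 5.0)
        assert m.sigma_a == pytest.approx(math.sqrt(2), rel=1e-12)
        assert m.sigma_b == pytest.approx(math.sqrt(2), rel=1e-12)
        assert (m.prior_a, m.prior_b) == (0.5, 0.5)

    def test_orientation_autodetected(self):
        m = fit_model([5.0, 6.0, 0.0, 1.0], ["NE", "NE", "non-NE", "non-NE"])
        assert m.class_b == "NE" and m.class_a == "non-NE"

    def test_empirical_priors(self):
        m = fit_model([0, 1, 2, 5, 6], ["a"] * 3 + ["b"] * 2, priors="empirical")
        assert m.prior_a == pytest.approx(0.6)
        assert m.prior_b == pytest.approx(0.4)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(7)
        xa = rng.normal(0.9, 1.3, 10_000)
        xb = rng.normal(5.8, 1.3, 10_000)
        m = fit_model(np.r_[xa, xb], ["non-NE"] * 10_000 + ["NE"] * 10_000)
        assert m.mu_a == pytest.approx(0.9, abs=0.05)
        assert m.mu_b == pytest.approx(5.8, abs=0.05)
        assert m.sigma_a == pytest.approx(1.3, abs=0.05)
        assert m.sigma_b == pytest.approx(1.3, abs=0.05)


class TestPosteriorOdds:
    def test_midpoint_symmetry(self):
        m = symmetric_model()
        assert posterior_odds(m, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_log_odds(self):
        # for N(0,1) vs N(4,1): log-odds = 4x - 8
        m = symmetric_model()
        x = (8 + LN9) / 4
        assert posterior_odds(m, x) == pytest.approx(9.0, rel=1e-9)
        assert posterior_odds(m, 4.0) == pytest.approx(math.exp(8.0), rel=1e-9)

    def test_infinite_score_rejected(self):
        with pytest.raises(ValidationError):
            posterior_odds(symmetric_model(), math.inf)

    def test_monotone_between_means_for_equal_sigmas(self):
        m = symmetric_model()
        xs = np.linspace(0, 4, 50)
        lo = log_posterior_odds(m, xs)
        assert np.all(np.diff(lo) > 0)


class TestSolveThresholds:
    def test_symmetric_closed_form(self):
        thr = solve_thresholds(symmetric_model(), 9.0)
        assert thr.chi_mid == pytest.approx(2.0, abs=1e-9)
        assert thr.chi_high == pytest.approx((8 + LN9) / 4, abs=1e-9)
        assert thr.chi_low == pytest.approx((8 - LN9) / 4, abs=1e-9)

    @pytest.mark.parametrize("model", [
        symmetric_model(),
        GaussianClassModel("a", "b", 0.0, 1.0, 4.0, 2.0),
        GaussianClassModel("a", "b", 0.13, 2.39, 5.57, 1.83),
        GaussianClassModel("a", "b", 1.0, 0.7, 5.0, 1.1, prior_a=0.4, prior_b=0.6),
    ])
    def test_agrees_with_bisection_oracle(self, model):
        thr = solve_thresholds(model, 9.0)
        lo, hi = min(model.mu_a, model.mu_b) - 8, max(model.mu_a, model.mu_b) + 8
        for target, x in zip((-LN9, 0.0, LN9), thr.as_tuple()):
            f = lambda t: log_posterior_odds(model, t) - target
            oracle = brentq(f, lo, x + 1e-6) if f(lo) < 0 else brentq(f, x - 1e-6, hi)
            assert x == pytest.approx(oracle, abs=1e-7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(mu_a=st.floats(-3, 3), sep=st.floats(0.5, 8),
           sigma_a=st.floats(0.3, 3), sigma_b=st.floats(0.3, 3))
    def test_round_trip_and_ordering(self, mu_a, sep, sigma_a, sigma_b):
        model = GaussianClassModel("a", "b", mu_a, sigma_a, mu_a + sep, sigma_b)
        try:
            thr = solve_thresholds(model, 9.0)
        except ThresholdSolveError:
            return  # pathological sigma ratios are allowed to refuse
        assert thr.chi_low <= thr.chi_mid <= thr.chi_high
        for target, x in zip((-LN9, 0.0, LN9), thr.as_tuple()):
            assert abs(log_posterior_odds(model, x) - target) < 1e-9

    def test_equal_variance_path_matches_quadratic_solver(self):
        base = solve_thresholds(symmetric_model(), 9.0)
        for eps in (1e-10, 1e-12):
            near = GaussianClassModel("a", "b", 0.0, 1.0, 4.0, 1.0 + eps)
            thr = solve_thresholds(near, 9.0)
            assert thr.chi_mid == pytest.approx(base.chi_mid, abs=1e-6)
            assert thr.chi_high == pytest.approx(base.chi_high, abs=1e-6)

    def test_odds_level_must_exceed_one(self):
        from mirdiag.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            solve_thresholds(symmetric_model(), 1.0)


class TestBoxes:
    @pytest.mark.parametrize("x,box", [
        (5.5, "strong_b"),   # confident NE call above chi 90:10 = 4.9
        (4.0, "weak_b"),
        (2.0, "weak_a"),
        (0.5, "strong_a"),
        (4.9, "weak_b"),     # exactly at a cut -> lower box
        (3.0, "weak_a"),
        (1.4, "strong_a"),
    ])
    def test_published_threshold_assignments(self, x, box):
        assert assign_box(x, PUBLISHED_THRESHOLDS) == box

    def test_classify_sample_fills_posteriors(self):
        m = symmetric_model()
        thr = solve_thresholds(m)
        call = classify_sample(2.0, thr, m, sample_id="S1")
        assert call.box == "weak_a"
        assert call.posterior_b == pytest.approx(0.5, abs=1e-12)
        assert call.odds_b_over_a == pytest.approx(1.0, abs=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdSet(3.0, 1.0, 5.0)

    def test_threshold_serialization_roundtrip(self, tmp_path):
        path = tmp_path / "thr.json"
        PUBLISHED_THRESHOLDS.to_json(path)
        assert ThresholdSet.from_json(path) == PUBLISHED_THRESHOLDS
        assert ThresholdSet.from_string("4.9,1.4,3") == PUBLISHED_THRESHOLDS


class TestBayesMaxAccuracy:
    def test_indistinguishable_classes(self):
        m = GaussianClassModel("a", "b", 2.0, 1.0, 2.0, 1.0)
        assert bayes_max_accuracy(m) == pytest.approx(0.5, abs=1e-12)

    def test_equal_variance_closed_form(self):
        # accuracy = 1 - Phi(-d/2) for separation d in SD units
        for d in (0.5, 1.0, 2.0, 4.0):
            m = GaussianClassModel("a", "b", 0.0, 1.0, d, 1.0)
            assert bayes_max_accuracy(m) == pytest.approx(
                1 - norm.cdf(-d / 2), abs=1e-9)

    @pytest.mark.parametrize("model", [
        GaussianClassModel("a", "b", 0.0, 1.0, 4.0, 2.0),
        GaussianClassModel("a", "b", 0.13, 2.39, 5.57, 1.83),
        GaussianClassModel("a", "b", 0.0, 2.0, 1.0, 0.5, prior_a=0.7, prior_b=0.3),
    ])
    def test_matches_quadrature_oracle(self, model):
        xs = np.linspace(-25, 30, 2_000_001)
        fa = model.prior_a * norm.pdf(xs, model.mu_a, model.sigma_a)
        fb = model.prior_b * norm.pdf(xs, model.mu_b, model.sigma_b)
        oracle = np.trapezoid(np.maximum(fa, fb), xs)
        assert bayes_max_accuracy(model) == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(sep=st.floats(0, 6), sigma_b=st.floats(0.3, 3),
           prior_a=st.floats(0.1, 0.9))
    def test_never_below_larger_prior(self, sep, sigma_b, prior_a):
        m = GaussianClassModel("a", "b", 0.0, 1.0, sep, sigma_b,
                               prior_a=prior_a, prior_b=1 - prior_a)
        assert bayes_max_accuracy(m) >= max(prior_a, 1 - prior_a) - 1e-12


class TestEstimatorAPI:
    def make_xy(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = np.r_[rng.normal(0.9, 1.3, n), rng.normal(5.8, 1.3, n)]
        y = np.array(["non-NE"] * n + ["NE"] * n)
        return x.reshape(-1, 1), y

    def test_fit_predict_matches_chi_mid_rule(self):
        X, y = self.make_xy()
        clf = GaussianBayesClassifier().fit(X, y)
        pred = clf.predict(X)
        manual = np.where(X[:, 0] > clf.thresholds_.chi_mid, "NE", "non-NE")
        assert (pred == manual).all()

    def test_predict_proba_rows_sum_to_one(self):
        X, y = self.make_xy()
        clf = GaussianBayesClassifier().fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        b_col = list(clf.classes_).index("NE")
        assert np.all(np.diff(proba[np.argsort(X[:, 0]), b_col]) >= -1e-12)

    def test_threshold_override_bypasses_fitting(self):
        X, y = self.make_xy()
        clf = GaussianBayesClassifier(thresholds=(1.4, 3.0, 4.9)).fit(X, y)
        assert clf.thresholds_.as_tuple() == (1.4, 3.0, 4.9)
        assert clf.predict_box([[5.5]])[0] == "strong_b"

    def test_clone_and_get_params(self):
        clf = GaussianBayesClassifier(priors="empirical", odds_level=4.0)
        params = clf.get_params()
        assert params["priors"] == "empirical" and params["odds_level"] == 4.0
        clone(clf)  # sklearn-compatible construction

    def test_score_is_accuracy(self):
        X, y = self.make_xy()
        clf = GaussianBayesClassifier().fit(X, y)
        acc = clf.score(X, y)
        assert acc == (clf.predict(X) == y).mean()

    def test_monte_carlo_accuracy_near_bayes_bound(self):
        rng = np.random.default_rng(123)
        n = 100_000
        m = GaussianClassModel("a", "b", 0.0, 1.0, 2.0, 1.0)
        x = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        y = np.array(["a"] * n + ["b"] * n)
        thr = solve_thresholds(m)
        pred = np.where(x > thr.chi_mid, "b", "a")
        acc = (pred == y).mean()
        assert abs(acc - bayes_max_accuracy(m)) < 0.005
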