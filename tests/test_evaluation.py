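import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirdiag.classifier import BOXES, ClassCall
from mirdiag.errors import InsufficientDataError, ValidationError
from mirdiag.evaluation import (ConfusionTable, classification_metrics,
                                confusion_table, empirical_roc_auc,
                                normalizer_stability, separation_t_test,
                                stage_anova)
from mirdiag.fixtures import SUBTYPE_CLASS_MAP, default_cohort_spec
from mirdiag.simulate import generate_cohort


def brute_force_auc(scores, labels, pos_label):
    """All-pairs Mann-Whitney oracle (ties count one half)."""
    pos = np.asarray(scores)[np.asarray(labels) == pos_label]
    neg = np.asarray(scores)[np.asarray(labels) != pos_label]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionTable:
    def test_published_fixture_row_sums(self, published_table):
        assert published_table.row_sums() == {"AD": 14, "SQC": 13, "AT": 8, "TC": 23}
        assert published_table.total == 58

    def test_tsv_roundtrip_unchanged(self, published_table, tmp_path):
        path = tmp_path / "confusion.tsv"
        published_table.to_tsv(path)
        back = ConfusionTable.from_tsv(path, SUBTYPE_CLASS_MAP, "non-NE", "NE")
        pd.testing.assert_frame_equal(back.counts, published_table.counts)

    def test_counts_conserved_under_collapse(self, published_table):
        assert int(published_table.collapse().to_numpy().sum()) == published_table.total

    def test_zero_calls_gives_all_zero_table(self):
        ct = confusion_table([], {}, SUBTYPE_CLASS_MAP, "non-NE", "NE",
                             subtype_order=["AD", "TC"])
        assert ct.total == 0 and (ct.counts.to_numpy() == 0).all()

    def test_unknown_subtype_is_validation_error(self):
        calls = [ClassCall("S1", 5.0, "strong_b", "NE")]
        with pytest.raises(ValidationError):
            confusion_table(calls, {"S1": "LCC"}, SUBTYPE_CLASS_MAP, "non-NE", "NE")

    def test_counts_from_calls(self):
        calls = [ClassCall("S1", 5.5, "strong_b", "NE"),
                 ClassCall("S2", 0.5, "strong_a", "non-NE"),
                 ClassCall("S3", 2.0, "weak_a", "non-NE")]
        subtypes = {"S1": "TC", "S2": "AD", "S3": "AD"}
        ct = confusion_table(calls, subtypes, SUBTYPE_CLASS_MAP, "non-NE", "NE")
        assert ct.counts.loc["TC", "strong_b"] == 1
        assert ct.counts.loc["AD", "strong_a"] == 1
        assert ct.counts.loc["AD", "weak_a"] == 1


class TestClassificationMetrics:
    def test_published_table_reproduces_published_rates(self, published_table):
        m = classification_metrics(published_table)
        assert m.accuracy_all == pytest.approx(100 * 53 / 58)
        assert m.rate_class_a == pytest.approx(100 * 25 / 27)   # "sensitivity"
        assert m.rate_class_b == pytest.approx(100 * 28 / 31)   # "specificity"
        assert m.sensitivity == m.rate_class_a
        assert m.specificity == m.rate_class_b

    def test_high_reliability_counts_confident_calls_only(self, published_table):
        m = classification_metrics(published_table)
        # strong boxes hold 19 + 6 = 25 calls of which 24 are correct
        assert m.n_high_reliability == 25
        assert m.accuracy_high_reliability == pytest.approx(100 * 24 / 25)

    def test_perfect_diagonal_table(self):
        counts = pd.DataFrame(
            {"strong_a": [10, 0], "weak_a": [5, 0],
             "weak_b": [0, 7], "strong_b": [0, 8]},
            index=pd.Index(["AD", "TC"], name="subtype"))
        ct = ConfusionTable(counts, SUBTYPE_CLASS_MAP, "non-NE", "NE")
        m = classification_metrics(ct)
        assert m.accuracy_all == 100.0
        assert m.rate_class_a == 100.0 and m.rate_class_b == 100.0
        assert m.accuracy_high_reliability == 100.0

    def test_empty_table_raises(self):
        counts = pd.DataFrame({b: [0] for b in BOXES},
                              index=pd.Index(["AD"], name="subtype"))
        ct = ConfusionTable(counts, SUBTYPE_CLASS_MAP, "non-NE", "NE")
        with pytest.raises(InsufficientDataError):
            classification_metrics(ct)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=8, max_size=8))
    def test_accuracy_is_class_size_weighted_mean_of_rates(self, counts):
        arr = np.array(counts).reshape(2, 4)
        table = pd.DataFrame(arr, columns=list(BOXES),
                             index=pd.Index(["AD", "TC"], name="subtype"))
        ct = ConfusionTable(table, SUBTYPE_CLASS_MAP, "non-NE", "NE")
        n_a, n_b = arr[0].sum(), arr[1].sum()
        if n_a == 0 or n_b == 0:
            return
        m = classification_metrics(ct)
        weighted = (n_a * m.rate_class_a + n_b * m.rate_class_b) / (n_a + n_b)
        assert m.accuracy_all == pytest.approx(weighted, abs=1e-9)


class TestROC:
    def test_perfect_separation(self):
        _, auc = empirical_roc_auc([1, 2, 3, 10, 11, 12],
                                   ["a", "a", "a", "b", "b", "b"], pos_label="b")
        assert auc == 1.0

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=4000)
        y = np.array(["a", "b"] * 2000)
        _, auc = empirical_roc_auc(x, y, pos_label="b")
        assert 0.47 < auc < 0.53

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(18)
        # include ties via rounding
        x = np.round(np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)], 1)
        y = np.array(["a"] * 100 + ["b"] * 100)
        _, auc = empirical_roc_auc(x, y, pos_label="b")
        assert auc == pytest.approx(brute_force_auc(x, y, "b"), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        x = np.r_[rng.normal(0, 1, 200), rng.normal(2, 1, 200)]
        y = np.array(["a"] * 200 + ["b"] * 200)
        _, auc1 = empirical_roc_auc(x, y, "b")
        _, auc2 = empirical_roc_auc(np.exp(0.5 * x), y, "b")
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_roc_points_span_unit_square(self):
        points, _ = empirical_roc_auc([1, 2, 3, 4], ["a", "b", "a", "b"], "b")
        assert points["fpr"].iloc[0] == 0 and points["tpr"].iloc[0] == 0
        assert points["fpr"].iloc[-1] == 1 and points["tpr"].iloc[-1] == 1

    def test_single_class_raises(self):
        with pytest.raises(InsufficientDataError):
            empirical_roc_auc([1, 2], ["a", "a"], pos_label="b")


class TestTTestAndAnova:
    def test_identical_groups_t_zero(self):
        t, p = separation_t_test([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_pooled_t(self):
        # {0,2} vs {4,6}: pooled s^2 = 2, se = sqrt2 -> |t| = 4/sqrt2
        t, p = separation_t_test([0, 2, 4, 6], ["a", "a", "b", "b"])
        assert abs(t) == pytest.approx(2 * np.sqrt(2), rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(2), 2), rel=1e-9)

    def test_strong_separation_on_study_like_cohort(self):
        spec = default_cohort_spec(seed=20, n_per_class={"non-NE": 200, "NE": 200})
        table = generate_cohort(spec)
        dct = (table[table["assay"] == "U6"].groupby("sample_id", sort=False)["ct"].mean()
               - table[table["assay"] == "miR375"].groupby("sample_id", sort=False)["ct"].mean())
        cls = table.groupby("sample_id", sort=False)["class"].first()
        _, p = separation_t_test(dct.to_numpy(), cls.to_numpy())
        assert p < 1e-10

    def test_anova_f_zero_for_identical_groups(self):
        f, p = stage_anova([1, 2, 1, 2, 1, 2], ["I", "I", "II", "II", "III", "III"])
        assert f == 0.0

    def test_anova_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(), 1, rng.integers(3, 10))
                      for _ in range(k)]
            x = np.concatenate(groups)
            g = np.concatenate([[f"g{i}"] * len(grp) for i, grp in enumerate(groups)])
            f, p = stage_anova(x, g)
            # brute-force one-way ANOVA from sums of squares
            grand = x.mean()
            ss_between = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
            ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
            df_b, df_w = k - 1, len(x) - k
            f_oracle = (ss_between / df_b) / (ss_within / df_w)
            assert f == pytest.approx(f_oracle, abs=1e-10)

    def test_anova_null_calibration(self):
        rng = np.random.default_rng(24)
        rejections = 0
        for _ in range(100):
            x = rng.normal(0, 1, 600)
            g = np.repeat(["I", "II", "III"], 200)
            _, p = stage_anova(x, g)
            rejections += p < 0.05
        assert rejections <= 10  # p > 0.05 in >= 90/100 null runs

    def test_anova_needs_two_groups(self):
        with pytest.raises(InsufficientDataError):
            stage_anova([1, 2, 3], ["I", "I", "I"])


class TestNormalizerStability:
    def test_identical_distributions_stable(self):
        rng = np.random.default_rng(25)
        x = rng.normal(24, 1, 60)
        y = np.repeat(["non-NE", "NE"], 30)
        rep = normalizer_stability(x, y, "non-NE", "NE")
        assert rep.stable

    def test_three_cycle_shift_flagged_unstable(self):
        rng = np.random.default_rng(26)
        x = np.r_[rng.normal(24, 0.3, 30), rng.normal(27, 0.3, 30)]
        y = np.repeat(["non-NE", "NE"], 30)
        rep = normalizer_stability(x, y, "non-NE", "NE")
        assert not rep.stable
        assert rep.delta_mean == pytest.approx(3.0, abs=0.3)

    def test_default_cohort_normalizer_stable_across_seeds(self):
        stable = 0
        for seed in range(100):
            spec = default_cohort_spec(seed=seed)
            table = generate_cohort(spec)
            u6 = table[table["assay"] == "U6"].groupby(
                "sample_id", sort=False)["ct"].mean()
            cls = table.groupby("sample_id", sort=False)["class"].first()
            rep = normalizer_stability(u6.to_numpy(), cls.to_numpy(), "non-NE", "NE")
            stable += rep.stable
        assert stable >= 95
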