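"""Patient-wise cross-validation, contingency tables and metric algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reims.simulate import balanced_design, generate_cohort
from reims.validation import (
    ContingencyTable,
    collapse_binary,
    lopo_cv,
    metrics,
    reconstruct_from_summary,
    sample_level_rule,
    tabulate,
)

from .conftest import COARSE_AXIS


class TestCollapseBinary:
    def test_three_class_mapping(self):
        assert collapse_binary(["tumour", "adenoma", "normal"]) == [
            "disease",
            "disease",
            "no_disease",
        ]

    def test_already_collapsed_labels_rejected(self):
        with pytest.raises(ValueError, match="cannot collapse"):
            collapse_binary(["disease"])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(["normal", "adenoma", "tumour"]), min_size=2, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_collapse_commutes_with_tabulation(self, truth, seed):
        rng = np.random.default_rng(seed)
        preds = [rng.choice(["normal", "adenoma", "tumour"]) for _ in truth]
        three = tabulate(preds, truth, ("adenoma", "normal", "tumour"))
        mapping = {"adenoma": "disease", "tumour": "disease", "normal": "no_disease"}
        merged = three.collapse(mapping, ("disease", "no_disease"))
        direct = tabulate(
            collapse_binary(preds), collapse_binary(truth), ("disease", "no_disease")
        )
        np.testing.assert_array_equal(merged.counts, direct.counts)


class TestTabulateAndMetrics:
    def test_published_style_2x2(self):
        """TP=130 FN=15 FP=8 TN=113 gives 91.4% accuracy, 94.2% PPV, 88.3% NPV."""
        t = ContingencyTable(("disease", "no_disease"), np.array([[130, 15], [8, 113]]))
        m = metrics(t)
        assert round(m.accuracy, 1) == 91.4
        assert round(m.ppv, 1) == 94.2
        assert round(m.npv, 1) == 88.3
        assert round(m.sensitivity, 1) == 89.7
        assert round(m.specificity, 1) == 93.4
        assert round(m.fnr, 1) == 10.3

    def test_perfect_predictions(self):
        t = ContingencyTable(("disease", "no_disease"), np.array([[10, 0], [0, 7]]))
        m = metrics(t)
        assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv) == (
            100.0,
        ) * 5

    def test_empty_truth_class_gives_nan_not_zero(self):
        t = ContingencyTable(("disease", "no_disease"), np.array([[0, 0], [2, 5]]))
        m = metrics(t)
        assert np.isnan(m.sensitivity) and np.isnan(m.fnr)
        assert m.specificity == pytest.approx(100 * 5 / 7)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metrics_match_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        truth = [str(rng.choice(["disease", "no_disease"])) for _ in range(n)]
        preds = [str(rng.choice(["disease", "no_disease"])) for _ in range(n)]
        t = tabulate(preds, truth, ("disease", "no_disease"))
        tp = sum(1 for p, q in zip(preds, truth) if p == q == "disease")
        tn = sum(1 for p, q in zip(preds, truth) if p == q == "no_disease")
        m = metrics(t)
        assert m.accuracy == pytest.approx(100 * (tp + tn) / n)
        row_sums = t.counts.sum(axis=1)
        assert row_sums[0] == truth.count("disease")
        col_sums = t.counts.sum(axis=0)
        assert col_sums[0] == preds.count("disease")


class TestReconstruction:
    def test_printed_summary_inverts_to_integer_table(self):
        t = reconstruct_from_summary(145, 121, 89.7, 93.4)
        np.testing.assert_array_equal(t.counts, [[130, 15], [8, 113]])

    def test_perfect_summary_gives_diagonal(self):
        t = reconstruct_from_summary(10, 20, 100.0, 100.0)
        np.testing.assert_array_equal(t.counts, [[10, 0], [0, 20]])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_inverse_of_metrics_on_random_tables(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        tp, tn = int(rng.integers(0, n_pos + 1)), int(rng.integers(0, n_neg + 1))
        t = ContingencyTable(
            ("disease", "no_disease"),
            np.array([[tp, n_pos - tp], [n_neg - tn, tn]]),
        )
        m = metrics(t)
        rebuilt = reconstruct_from_summary(n_pos, n_neg, m.sensitivity, m.specificity)
        np.testing.assert_array_equal(rebuilt.counts, t.counts)


class TestSampleLevelRule:
    def test_any_disease_spectrum_flags_the_sample(self):
        calls = sample_level_rule(
            ["no_disease", "disease", "no_disease"], ["a", "a", "a"]
        )
        assert calls == {"a": "disease"}

    def test_all_negative_sample(self):
        calls = sample_level_rule(["no_disease", "no_disease"], ["a", "a"])
        assert calls == {"a": "no_disease"}

    def test_sample_level_npv_dominates_spectrum_level(self):
        """With >= 2 spectra per diseased sample and independent errors, the
        any-positive rule can only raise the negative predictive value."""
        rng = np.random.default_rng(99)
        violations = 0
        for _ in range(50):
            n_samples = 30
            truths, s_preds, s_truth, sids = {}, [], [], []
            for i in range(n_samples):
                truth = "disease" if i < 15 else "no_disease"
                truths[f"s{i}"] = truth
                k = int(rng.integers(2, 5))
                for _ in range(k):
                    if truth == "disease":
                        pred = "disease" if rng.uniform() < 0.85 else "no_disease"
                    else:
                        pred = "no_disease" if rng.uniform() < 0.9 else "disease"
                    s_preds.append(pred)
                    s_truth.append(truth)
                    sids.append(f"s{i}")

            def npv(preds, truth):
                tn = sum(1 for p, t in zip(preds, truth) if p == t == "no_disease")
                neg = sum(1 for p in preds if p == "no_disease")
                return tn / neg if neg else np.nan

            spectrum_npv = npv(s_preds, s_truth)
            calls = sample_level_rule(s_preds, sids)
            sample_npv = npv(
                [calls[s] for s in calls], [truths[s] for s in calls]
            )
            if not np.isnan(spectrum_npv) and not np.isnan(sample_npv):
                if sample_npv < spectrum_npv - 1e-12:
                    violations += 1
        assert violations == 0


class TestLopoCv:
    def test_no_fold_predicts_its_own_training_patient(self, small_cohort):
        res = lopo_cv(small_cohort, axis=COARSE_AXIS)
        by_id = {s.spectrum_id: s.patient_id for s in small_cohort}
        for sid, fold_patient in res.fold_of_spectrum.items():
            assert by_id[sid] == fold_patient  # held out exactly in own fold
        assert len(res.predictions) == len(small_cohort)

    def test_single_patient_rejected(self, small_cohort):
        ours = [s for s in small_cohort if s.patient_id == "p01"]
        with pytest.raises(ValueError, match=">= 2 patients"):
            lopo_cv(ours)

    def test_fold_without_two_classes_is_skipped_with_warning(self):
        d = balanced_design(
            n_patients_per_class=1, spectra_per_sample=4, classes=("normal", "tumour"), seed=3
        )
        cohort = generate_cohort(d)
        with pytest.warns(UserWarning, match="skipped"):
            res = lopo_cv(cohort, axis=COARSE_AXIS)
        assert set(res.skipped_folds) == {"p01", "p02"}
        assert res.predictions == []

    def test_strong_effect_cohort_is_learnable(self, small_cohort):
        res = lopo_cv(small_cohort, axis=COARSE_AXIS, binary=True)
        t = tabulate(res.predicted_labels(), res.truth, ("disease", "no_disease"))
        assert t.accuracy() >= 80.0
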