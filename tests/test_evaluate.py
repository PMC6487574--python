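"""Metrics, macro aggregation, misprediction taxonomy, association tests."""

import numpy as np
import pytest

from origincall.evaluate import (
    ClassCounts,
    association_tests,
    confident_subset,
    confusion_counts,
    evaluation_report,
    f1,
    fpr,
    load_metastatic_worked_example,
    macro_metrics,
    misprediction_category,
    overall_accuracy,
    precision,
    recall,
)
from origincall.io import SampleMetadata


def brute_force_counts(truth, pred, cls):
    """Independent oracle: enumerate every (truth, prediction) pair."""
    tp = tn = fp = fn = 0
    for t, p in zip(truth, pred):
        if t == cls and p == cls:
            tp += 1
        elif t == cls:
            fn += 1
        elif p == cls:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionCounts:
    def test_small_enumerated_example(self):
        c = confusion_counts(["A", "A", "B"], ["A", "B", "B"], "A")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 1)

    def test_perfect_prediction_has_no_errors(self):
        truth = ["A", "B", "C", "B"]
        for cls in "ABC":
            c = confusion_counts(truth, truth, cls)
            assert c.fp == 0 and c.fn == 0

    def test_absent_class_is_all_true_negatives(self):
        c = confusion_counts(["A", "B"], ["B", "A"], "Z")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_counts(["A"], ["A", "B"], "A")

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        classes = list("ABCD")
        for _ in range(1000):
            n = rng.integers(1, 21)
            truth = rng.choice(classes, size=n)
            pred = rng.choice(classes, size=n)
            for cls in classes:
                c = confusion_counts(truth, pred, cls)
                assert (c.tp, c.tn, c.fp, c.fn) == tuple(
                    np.array(brute_force_counts(truth, pred, cls))[[0, 1, 2, 3]]
                )
                # derived metrics against direct formulas
                tp, tn, fp_, fn_ = brute_force_counts(truth, pred, cls)
                assert precision(c) == (tp / (tp + fp_) if tp + fp_ else 0.0)
                assert recall(c) == (tp / (tp + fn_) if tp + fn_ else 0.0)
                assert fpr(c) == (fp_ / (fp_ + tn) if fp_ + tn else 0.0)


class TestMetricFormulas:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,p,r,f",
        [
            (17, 114, 0, 4, 1.00, 0.81, 0.89),  # colorectal, metastatic biopsies
            (2, 129, 0, 3, 1.00, 0.40, 0.57),  # endometrial carcinoma, metastatic
            (63, 68, 2, 2, 0.97, 0.97, 0.97),  # breast carcinoma, metastatic
            (9, 122, 1, 8, 0.90, 0.53, 0.67),  # sarcoma, metastatic
            (0, 29, 0, 1, 0.00, 0.00, 0.00),  # never-called class: flagged zeros
        ],
    )
    def test_worked_examples_round_to_reported_values(self, tp, tn, fp, fn, p, r, f):
        c = ClassCounts("x", tp=tp, tn=tn, fp=fp, fn=fn)
        assert round(precision(c), 2) == p
        assert round(recall(c), 2) == r
        assert round(f1(c), 2) == f

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            c = ClassCounts("x", *rng.integers(0, 50, size=4))
            lo, hi = sorted([precision(c), recall(c)])
            assert lo * (1 - 1e-12) <= f1(c) <= hi * (1 + 1e-12) or f1(c) == 0.0

    def test_macro_is_unweighted_mean(self):
        mean, sd = macro_metrics([1.0, 0.5])
        assert mean == 0.75
        mean, sd = macro_metrics([0.4, 0.4, 0.4])
        assert mean == pytest.approx(0.4)
        assert sd == pytest.approx(0.0)

    def test_macro_invariant_to_class_order(self):
        values = [0.9, 0.1, 0.5, 0.7]
        assert macro_metrics(values) == macro_metrics(values[::-1])

    @pytest.mark.parametrize(
        "truth,pred,expected",
        [(["A", "A", "B", "B"], ["A", "B", "B", "B"], 0.75),
         (["A", "B"], ["A", "B"], 1.0),
         (["A", "B"], ["B", "A"], 0.0)],
    )
    def test_overall_accuracy(self, truth, pred, expected):
        assert overall_accuracy(truth, pred) == expected


class TestConfidentSubset:
    def test_enumerated_example(self):
        n, acc = confident_subset([0.9, 0.9, 0.7, 0.5], [True, True, False, True], 0.8)
        assert (n, acc) == (2, 1.0)

    def test_threshold_zero_is_overall(self):
        n, acc = confident_subset([0.2, 0.4], [True, False], 0.0)
        assert (n, acc) == (2, 0.5)

    def test_empty_subset_flagged_undefined(self):
        n, acc = confident_subset([0.5, 0.6], [True, True], 1.0)
        assert n == 0 and acc is None


class TestMispredictionTaxonomy:
    ORGAN_MAP = {
        "breast_ca": "breast",
        "hepatocellular_ca": "liver_gi",
        "stomach_ac": "upper_gi",
        "esophageal_ac": "upper_gi",
    }

    def test_correct_call_is_diagnosis(self):
        assert misprediction_category("breast_ca", "breast_ca") == "diagnosis"

    def test_biopsy_site_match(self):
        # liver cancer called on a breast-cancer sample biopsied from the liver
        meta = SampleMetadata(
            sample_id="s", class_label="breast_ca", biopsy_site_class="hepatocellular_ca"
        )
        assert (
            misprediction_category("hepatocellular_ca", "breast_ca", meta, self.ORGAN_MAP)
            == "biopsy_site"
        )

    def test_organ_system_match(self):
        assert (
            misprediction_category("esophageal_ac", "stomach_ac", None, self.ORGAN_MAP)
            == "organ_system"
        )

    def test_priority_biopsy_site_before_organ_system(self):
        meta = SampleMetadata(
            sample_id="s", class_label="stomach_ac", biopsy_site_class="esophageal_ac"
        )
        assert (
            misprediction_category("esophageal_ac", "stomach_ac", meta, self.ORGAN_MAP)
            == "biopsy_site"
        )

    def test_unexplained_is_other(self):
        assert (
            misprediction_category("breast_ca", "stomach_ac", None, self.ORGAN_MAP)
            == "other"
        )

    def test_missing_organ_map_entry_warns_and_falls_through(self):
        with pytest.warns(UserWarning, match="no entry"):
            category = misprediction_category(
                "unknown_class", "stomach_ac", None, self.ORGAN_MAP
            )
        assert category == "other"


class TestEvaluationReport:
    def test_count_identities(self):
        rng = np.random.default_rng(17)
        truth = rng.choice(list("ABC"), size=60)
        pred = rng.choice(list("ABC"), size=60)
        report = evaluation_report(truth, pred)
        per = report.per_class.set_index("class")
        for cls in "ABC":
            assert per.loc[cls, "TP"] + per.loc[cls, "FN"] == np.sum(truth == cls)
        assert per["TP"].sum() == np.sum(truth == pred)
        assert (per[["TP", "TN", "FP", "FN"]].sum(axis=1) == 60).all()

    def test_rounded_table_two_decimals(self):
        report = evaluation_report(["A", "A", "B"], ["A", "B", "B"])
        rounded = report.rounded()
        assert (rounded["precision"] * 100 % 1 == 0).all()


class TestAssociationTests:
    def test_perfectly_correlated_class_size(self):
        acc = [0.2, 0.4, 0.6, 0.8]
        size = [20, 40, 60, 80]
        out = association_tests([True], class_accuracy=acc, class_size=size)
        assert out["pearson_class_size"]["statistic"] == pytest.approx(1.0)

    def test_constant_confidence_flagged(self):
        out = association_tests(
            [True, False, True], confidence=[0.5, 0.5, 0.5]
        )
        assert not out["t_confidence"]["computable"]

    def test_confidence_separation_is_significant(self):
        correct = [True] * 30 + [False] * 30
        conf = list(np.linspace(0.8, 1.0, 30)) + list(np.linspace(0.2, 0.4, 30))
        out = association_tests(correct, confidence=conf)
        assert out["t_confidence"]["computable"]
        assert out["t_confidence"]["p"] < 1e-6

    def test_chi2_null_rarely_significant(self):
        # correctness independent of tumor content -> p > .05 in >= 90% of runs
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            correct = rng.uniform(size=200) < 0.85
            content = rng.uniform(20, 100, size=200)
            out = association_tests(correct, tumor_content=content)
            if out["chi2_content"]["computable"] and out["chi2_content"]["p"] <= 0.05:
                rejections += 1
        assert rejections <= 2

    def test_degenerate_chi2_margin_flagged(self):
        out = association_tests([True, True], tumor_content=[50.0, 60.0])
        assert not out["chi2_content"]["computable"]


class TestWorkedExampleTable:
    def test_bundled_table_shape_and_totals(self):
        table = load_metastatic_worked_example()
        rows = table[table["section"] != "total"]
        assert len(rows) == 23
        total = table[table["section"] == "total"].iloc[0]
        assert rows["total"].sum() == total["total"] == 201
        assert rows["tp"].sum() == total["tp"] == 160
        assert rows["fn"].sum() == total["fn"] == 41
        for col in ("n_diagnosis", "n_biopsy_site", "n_organ_system", "n_other"):
            assert rows[col].sum() == total[col]

    def test_category_counts_partition_each_row(self):
        table = load_metastatic_worked_example()
        rows = table[table["section"] != "total"]
        cats = rows[["n_diagnosis", "n_biopsy_site", "n_organ_system", "n_other"]]
        assert (cats.sum(axis=1) == rows["total"]).all()
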