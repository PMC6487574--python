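"""Diagnostic performance metrics, cohort aggregation, and misprediction taxonomy.

Metrics are one-vs-rest per class: precision TP/(TP+FP), recall TP/(TP+FN),
F1 the harmonic mean of the two, FPR FP/(FP+TN). The cohort-level summary is
the unweighted mean of the per-class values (macro averaging), reported with
its standard deviation. Overall accuracy is the fraction of correct calls.
A zero denominator yields a flagged 0.0 rather than an error, matching how
an empty-prediction class is conventionally reported.

Errant calls are categorized in priority order: the call matched the
pathology diagnosis (diagnosis — i.e. not actually errant), matched the
tissue type of the biopsy site (biopsy_site), matched a cancer of the same
organ system of origin (organ_system), or none of these (other).

A worked-example table from a published 201-sample metastatic validation
cohort (per-class one-vs-rest counts with the reported metrics) is bundled
for regression-testing the metric implementations; see
:func:`load_metastatic_worked_example`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata

__all__ = [
    "ClassCounts",
    "EvaluationReport",
    "confusion_counts",
    "precision",
    "recall",
    "f1",
    "fpr",
    "macro_metrics",
    "overall_accuracy",
    "confident_subset",
    "misprediction_category",
    "association_tests",
    "evaluation_report",
    "load_metastatic_worked_example",
]


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest confusion counts for a single class."""

    class_label: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(truth: Sequence, predicted: Sequence, class_label) -> ClassCounts:
    """One-vs-rest TP/TN/FP/FN for ``class_label``."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape} vs {predicted.shape}"
        )
    is_pos = truth == class_label
    called = predicted == class_label
    return ClassCounts(
        class_label=str(class_label),
        tp=int(np.sum(is_pos & called)),
        tn=int(np.sum(~is_pos & ~called)),
        fp=int(np.sum(~is_pos & called)),
        fn=int(np.sum(is_pos & ~called)),
    )


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def precision(c: ClassCounts) -> float:
    """TP/(TP+FP); flagged 0.0 when the class was never called."""
    return _safe_ratio(c.tp, c.tp + c.fp)


def recall(c: ClassCounts) -> float:
    """TP/(TP+FN), the true-positive rate."""
    return _safe_ratio(c.tp, c.tp + c.fn)


def f1(c: ClassCounts) -> float:
    """Harmonic mean of precision and recall; 0.0 when both are 0."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def fpr(c: ClassCounts) -> float:
    """FP/(FP+TN), the false-positive rate."""
    return _safe_ratio(c.fp, c.fp + c.tn)


def macro_metrics(per_class_values: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and SD of a per-class metric (the cohort metric)."""
    values = np.asarray(per_class_values, dtype=float)
    if values.size == 0:
        raise ValueError("macro metric of an empty value list")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def overall_accuracy(truth: Sequence, predicted: Sequence) -> float:
    """Fraction of correct calls over the whole cohort."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(truth == predicted))


def confident_subset(
    confidences: Sequence[float],
    correct: Sequence[bool],
    threshold: float = 0.80,
) -> tuple[int, float | None]:
    """Size and accuracy of the subset with confidence ≥ threshold.

    Returns ``(0, None)`` (accuracy undefined) when no call clears the
    threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    conf = np.asarray(confidences, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    mask = conf >= threshold
    n = int(mask.sum())
    if n == 0:
        return 0, None
    return n, float(correct[mask].mean())


def misprediction_category(
    predicted: str,
    truth: str,
    metadata: SampleMetadata | None = None,
    organ_map: Mapping[str, str] | None = None,
) -> str:
    """Categorize a call: diagnosis, biopsy_site, organ_system, or other.

    Categories are checked in that priority order. ``organ_map`` maps class
    codes to organ-system groups; if an entry is missing when needed, the
    category falls through to ``other`` with a warning.
    """
    if predicted == truth:
        return "diagnosis"
    if metadata is not None and metadata.biopsy_site_class is not None:
        if predicted == metadata.biopsy_site_class:
            return "biopsy_site"
    if organ_map is not None:
        gp, gt = organ_map.get(predicted), organ_map.get(truth)
        if gp is None or gt is None:
            missing = predicted if gp is None else truth
            warnings.warn(
                f"organ map has no entry for class {missing!r}; "
                f"categorizing as 'other'",
                stacklevel=2,
            )
        elif gp == gt:
            return "organ_system"
    return "other"


@dataclass
class EvaluationReport:
    """Per-class counts and metrics plus cohort-level summaries."""

    per_class: pd.DataFrame  # class, TP, TN, FP, FN, TPR, FPR, precision, recall, F1
    macro: dict  # metric -> (mean, sd)
    accuracy: float
    n_samples: int
    confidence_threshold: float | None = None
    n_confident: int | None = None
    confident_accuracy: float | None = None
    categories: pd.DataFrame | None = None  # sample_id, truth, predicted, category

    def rounded(self) -> pd.DataFrame:
        """Display table: metrics at 2 decimals (FPR at 3), raw counts kept."""
        out = self.per_class.copy()
        for col in ("TPR", "precision", "recall", "F1"):
            out[col] = out[col].round(2)
        out["FPR"] = out["FPR"].round(3)
        return out


def evaluation_report(
    truth: Sequence,
    predicted: Sequence,
    classes: Sequence | None = None,
    confidences: Sequence[float] | None = None,
    confidence_threshold: float = 0.80,
    metadata: Sequence[SampleMetadata] | None = None,
    organ_map: Mapping[str, str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Full evaluation of a prediction set against truth labels."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if classes is None:
        classes = sorted(set(truth))
    rows = []
    for cls in classes:
        c = confusion_counts(truth, predicted, cls)
        rows.append(
            {
                "class": c.class_label,
                "n": c.tp + c.fn,
                "TP": c.tp,
                "TN": c.tn,
                "FP": c.fp,
                "FN": c.fn,
                "TPR": recall(c),
                "FPR": fpr(c),
                "precision": precision(c),
                "recall": recall(c),
                "F1": f1(c),
                "zero_flagged": (c.tp + c.fp == 0) or (c.tp + c.fn == 0),
            }
        )
    per_class = pd.DataFrame(rows)
    macro = {
        metric: macro_metrics(per_class[metric].to_numpy())
        for metric in ("precision", "recall", "F1", "FPR")
    }
    correct = truth == predicted
    report = EvaluationReport(
        per_class=per_class,
        macro=macro,
        accuracy=overall_accuracy(truth, predicted),
        n_samples=len(truth),
    )
    if confidences is not None:
        n_conf, acc_conf = confident_subset(confidences, correct, confidence_threshold)
        report.confidence_threshold = confidence_threshold
        report.n_confident = n_conf
        report.confident_accuracy = acc_conf
    if metadata is not None or organ_map is not None:
        meta = list(metadata) if metadata is not None else [None] * len(truth)
        ids = (
            list(sample_ids)
            if sample_ids is not None
            else [m.sample_id if m else str(i) for i, m in enumerate(meta)]
        )
        cat_rows = []
        for i in range(len(truth)):
            cat_rows.append(
                {
                    "sample_id": ids[i],
                    "truth": truth[i],
                    "predicted": predicted[i],
                    "category": misprediction_category(
                        predicted[i], truth[i], meta[i], organ_map
                    ),
                }
            )
        report.categories = pd.DataFrame(cat_rows)
    return report


def association_tests(
    correct: Sequence[bool],
    confidence: Sequence[float] | None = None,
    tumor_content: Sequence[float] | None = None,
    class_accuracy: Sequence[float] | None = None,
    class_size: Sequence[int] | None = None,
    content_cut: float | None = None,
) -> dict:
    """The cohort-level association tests: χ², t, and Pearson correlation.

    * χ² of correctness against tumor content dichotomized at ``content_cut``
      (default: the cohort median).
    * Two-sample t of confidence in correct vs incorrect calls.
    * Pearson r of per-class accuracy against training class size.

    Degenerate inputs (an empty margin, constant confidence) are flagged
    ``not computable`` instead of raising.
    """
    correct = np.asarray(correct, dtype=bool)
    out: dict[str, dict] = {}
    if tumor_content is not None:
        content = np.asarray(tumor_content, dtype=float)
        cut = float(np.median(content)) if content_cut is None else content_cut
        high = content >= cut
        table = np.array(
            [
                [np.sum(correct & high), np.sum(correct & ~high)],
                [np.sum(~correct & high), np.sum(~correct & ~high)],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            out["chi2_content"] = {"computable": False, "reason": "empty margin"}
        else:
            res = stats.chi2_contingency(table)
            out["chi2_content"] = {
                "computable": True,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "cut": cut,
            }
    if confidence is not None:
        conf = np.asarray(confidence, dtype=float)
        a, b = conf[correct], conf[~correct]
        if len(a) == 0 or len(b) == 0 or (np.ptp(conf) == 0):
            out["t_confidence"] = {
                "computable": False,
                "reason": "a group is empty or confidence is constant",
            }
        else:
            res = stats.ttest_ind(a, b)
            out["t_confidence"] = {
                "computable": True,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
    if class_accuracy is not None and class_size is not None:
        acc = np.asarray(class_accuracy, dtype=float)
        size = np.asarray(class_size, dtype=float)
        if len(acc) < 3 or np.ptp(acc) == 0 or np.ptp(size) == 0:
            out["pearson_class_size"] = {
                "computable": False,
                "reason": "fewer than 3 classes or a constant vector",
            }
        else:
            res = stats.pearsonr(acc, size)
            out["pearson_class_size"] = {
                "computable": True,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
    return out


def load_metastatic_worked_example() -> pd.DataFrame:
    """The bundled metastatic-cohort worked example.

    One row per diagnosed class per biopsy-section (metastatic-site or
    primary-site biopsies): one-vs-rest counts (TP, TN, FP, FN), the
    reported two-decimal metrics, and the misprediction-category case
    counts. Rows with ``grouped == 1`` pool several cancer types; their
    reported precision/F1 were computed within the group and are NOT
    reproducible from the row's own pooled counts, so metric regression
    tests use only the ungrouped rows.
    """
    ref = resources.files("origincall.data").joinpath("metastatic_cohort_counts.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
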