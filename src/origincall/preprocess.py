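"""Train/test splitting, gene feature selection, and per-member linear scalings.

Two feature-selection strategies are provided for comparison against the
whole transcriptome: pairwise ANOVA of log-transformed training data (for
every unordered pair of classes, a per-gene F test with Bonferroni
correction across genes; genes are ranked by the number of class pairs they
significantly discriminate), and a fixed user-supplied gene list (e.g. a
curated cancer-gene catalogue).

The per-member linear transforms are affine per gene: standardization
(population sd), min-max, max-abs, robust (median/IQR), or identity.
Degenerate scales are replaced by 1 so constant genes pass through shifted
but unscaled. Transforms are always fitted on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import (
    MaxAbsScaler,
    MinMaxScaler,
    RobustScaler,
    StandardScaler,
)
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionMatrix, LabeledCohort, log_transform

__all__ = [
    "GeneSubset",
    "LinearTransform",
    "AnovaGeneSelector",
    "stratified_split",
    "anova_select",
    "fixed_list_select",
    "fit_transform",
    "apply_transform",
    "invert_transform",
    "TRANSFORM_KINDS",
]

TRANSFORM_KINDS = ("identity", "standard", "minmax", "maxabs", "robust")


@dataclass
class GeneSubset:
    """An ordered gene selection with its provenance."""

    gene_ids: list[str]
    method: str  # whole_transcriptome | anova | fixed_list
    scores: pd.DataFrame | None = None  # per-gene selection scores (anova only)
    n_missing: int = 0  # fixed_list: requested genes absent from the matrix


def stratified_split(
    cohort: LabeledCohort, train_fraction: float, seed: int
) -> tuple[LabeledCohort, LabeledCohort]:
    """Per-class split: round(n_class * fraction) samples to train, remainder to test.

    Rounding is half-away-from-zero. Classes with fewer than 2 samples go
    entirely to train, with a warning. Deterministic under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    labels = cohort.labels
    sample_ids = np.asarray(cohort.matrix.sample_ids, dtype=object)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in cohort.class_vocabulary:
        ids = sample_ids[labels == cls]
        if len(ids) < 2:
            warnings.warn(
                f"class {cls!r} has {len(ids)} sample(s); assigning all to train",
                stacklevel=2,
            )
            train_ids.extend(ids)
            continue
        n_train = int(np.floor(len(ids) * train_fraction + 0.5))
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return cohort.subset(train_ids), cohort.subset(test_ids)


class AnovaGeneSelector(SelectorMixin, BaseEstimator):
    """Select genes by pairwise one-way F tests between class pairs.

    For each unordered pair of classes, every gene gets a two-group one-way F
    test (equivalent to a pooled-variance t²) on log-scale expression; p
    values are Bonferroni-adjusted across genes within the pair. A gene's
    score is the number of pairs for which it is significant at ``alpha``.
    The selection is the top ``k`` genes by score, ties broken by the
    smaller minimum raw p value across pairs and then by gene identifier.
    Only genes with a positive score are ever selected.

    Parameters
    ----------
    k : int, default=3000
        Number of genes to keep (fewer if fewer genes score above zero).
    alpha : float, default=0.05
        Significance level applied to Bonferroni-adjusted p values.
    """

    def __init__(self, k: int = 3000, alpha: float = 0.05):
        self.k = k
        self.alpha = alpha

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float, ensure_min_samples=2)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("pairwise selection needs at least 2 classes")
        n_genes = X.shape[1]
        pair_counts = np.zeros(n_genes, dtype=int)
        min_p = np.ones(n_genes, dtype=float)
        n_pairs = 0
        for a, b in combinations(classes, 2):
            xa, xb = X[y == a], X[y == b]
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"class pair ({a!r}, {b!r}) skipped: a class has < 2 samples",
                    stacklevel=2,
                )
                continue
            n_pairs += 1
            with warnings.catch_warnings():
                # constant genes produce F = nan; treated as non-significant
                warnings.simplefilter("ignore")
                _, p = stats.f_oneway(xa, xb, axis=0)
            testable = np.isfinite(p)
            p = np.where(testable, p, 1.0)
            # Bonferroni across genes actually tested in this pair; untestable
            # (constant) genes do not inflate the correction
            p_adj = np.minimum(p * max(int(testable.sum()), 1), 1.0)
            pair_counts += p_adj < self.alpha
            min_p = np.minimum(min_p, p)
        if n_pairs == 0:
            raise ValueError("no class pair had enough samples for a test")
        self.pair_counts_ = pair_counts
        self.min_p_ = min_p
        self.n_pairs_tested_ = n_pairs
        gene_names = getattr(
            self, "feature_names_in_", np.array([str(i) for i in range(n_genes)])
        )
        order = np.lexsort((gene_names.astype(str), min_p, -pair_counts))
        positive = order[pair_counts[order] > 0]
        self.ranking_ = order
        self.selected_idx_ = np.sort(positive[: self.k])
        mask = np.zeros(n_genes, dtype=bool)
        mask[self.selected_idx_] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def anova_select(train: LabeledCohort, k: int = 3000, alpha: float = 0.05) -> GeneSubset:
    """Run :class:`AnovaGeneSelector` on a cohort (log-transforming if needed)."""
    matrix = train.matrix if train.matrix.log_scale else log_transform(train.matrix)
    selector = AnovaGeneSelector(k=k, alpha=alpha).fit(matrix.frame, train.labels)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    chosen = set(genes[selector.selected_idx_])
    ranked = [g for g in genes[selector.ranking_] if g in chosen]
    scores = pd.DataFrame(
        {
            "gene_id": genes,
            "n_significant_pairs": selector.pair_counts_,
            "min_p": selector.min_p_,
        }
    ).set_index("gene_id")
    return GeneSubset(gene_ids=ranked[: k], method="anova", scores=scores)


def fixed_list_select(cohort: LabeledCohort, gene_list: Sequence[str]) -> GeneSubset:
    """Restrict to a user-supplied gene list, preserving list order."""
    present = set(cohort.matrix.gene_ids)
    kept = [g for g in gene_list if g in present]
    missing = len(gene_list) - len(kept)
    if not kept:
        raise ValueError("none of the listed genes are present in the matrix")
    if missing:
        warnings.warn(f"{missing} listed genes absent from the matrix", stacklevel=2)
    return GeneSubset(gene_ids=kept, method="fixed_list", n_missing=missing)


_SCALERS = {
    "standard": lambda: StandardScaler(),
    "minmax": lambda: MinMaxScaler(),
    "maxabs": lambda: MaxAbsScaler(),
    "robust": lambda: RobustScaler(),
}


@dataclass
class LinearTransform:
    """A fitted per-gene affine transform: (x - offset) / scale."""

    kind: str
    gene_ids: list[str]
    offset: np.ndarray  # per-gene
    scale: np.ndarray  # per-gene, strictly positive

    def apply(self, frame: pd.DataFrame) -> np.ndarray:
        if list(frame.columns) != self.gene_ids:
            if set(frame.columns) != set(self.gene_ids):
                raise ValueError("matrix gene set does not match the fitted transform")
            frame = frame.loc[:, self.gene_ids]
        return (frame.to_numpy(dtype=float) - self.offset) / self.scale

    def apply_array(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.offset) / self.scale

    def invert(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.offset


def fit_transform(kind: str, train_matrix) -> LinearTransform:
    """Fit a linear transform of the given kind on training data only.

    ``train_matrix`` may be an :class:`ExpressionMatrix` or a DataFrame of
    samples × genes. Degenerate per-gene scales become 1.
    """
    if kind not in TRANSFORM_KINDS:
        raise ValueError(f"unknown transform kind {kind!r}; choose from {TRANSFORM_KINDS}")
    frame = train_matrix.frame if isinstance(train_matrix, ExpressionMatrix) else train_matrix
    genes = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    n_genes = X.shape[1]
    if kind == "identity":
        return LinearTransform(kind, genes, np.zeros(n_genes), np.ones(n_genes))
    scaler = _SCALERS[kind]().fit(X)
    if kind == "standard":
        offset, scale = scaler.mean_, scaler.scale_
    elif kind == "minmax":
        offset, scale = scaler.data_min_, scaler.data_range_.copy()
        scale[scale == 0] = 1.0
    elif kind == "maxabs":
        offset, scale = np.zeros(n_genes), scaler.scale_
    else:  # robust
        offset, scale = scaler.center_, scaler.scale_
    return LinearTransform(kind, genes, np.asarray(offset, float), np.asarray(scale, float))


def apply_transform(transform: LinearTransform, matrix) -> np.ndarray:
    frame = matrix.frame if isinstance(matrix, ExpressionMatrix) else matrix
    return transform.apply(frame)


def invert_transform(transform: LinearTransform, X: np.ndarray) -> np.ndarray:
    return transform.invert(X)
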