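"""Linear comparator classifier on ANOVA-selected features.

The baseline against which the ensemble is judged: multinomial logistic
regression (softmax over linear scores) with an l2 penalty, fitted on
standardized log-scale expression restricted to a selected gene subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionMatrix, LabeledCohort, log_transform
from .preprocess import GeneSubset, anova_select

__all__ = ["LinearBaselineClassifier", "train_linear", "predict_linear"]


class LinearBaselineClassifier(ClassifierMixin, BaseEstimator):
    """Multinomial logistic regression on standardized log-expression.

    Parameters
    ----------
    l2 : float, default=1e-2
        l2 penalty strength; must be strictly positive (the penalty is what
        keeps near-collinear expression data well-posed).
    max_iter : int, default=500
    random_state : int, default=0
    """

    def __init__(self, l2: float = 1e-2, max_iter: int = 500, random_state: int = 0):
        self.l2 = l2
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if self.l2 <= 0:
            raise ValueError("l2 penalty must be strictly positive")
        X, y = validate_data(self, X, y, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        self.model_ = LogisticRegression(
            C=1.0 / self.l2,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def _prepare(self, X):
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [g for g in self.feature_names_in_ if g not in X.columns]
            if missing:
                raise ValueError(
                    f"{len(missing)} model genes missing from input "
                    f"(first few: {missing[:5]})"
                )
            X = X.loc[:, list(self.feature_names_in_)]
        return validate_data(self, X, dtype=float, reset=False)

    def predict(self, X):
        return self.model_.predict(self.scaler_.transform(self._prepare(X)))

    def predict_proba(self, X):
        return self.model_.predict_proba(self.scaler_.transform(self._prepare(X)))


def train_linear(
    train: LabeledCohort,
    subset: GeneSubset | None = None,
    l2: float = 1e-2,
    seed: int = 0,
    anova_k: int = 3000,
) -> tuple[LinearBaselineClassifier, GeneSubset]:
    """Train the baseline on a cohort, selecting features by ANOVA if not given."""
    if subset is None:
        subset = anova_select(train, k=anova_k)
    if not subset.gene_ids:
        raise ValueError("empty gene subset")
    matrix = train.matrix if train.matrix.log_scale else log_transform(train.matrix)
    frame = matrix.frame.loc[:, subset.gene_ids]
    model = LinearBaselineClassifier(l2=l2, random_state=seed).fit(frame, train.labels)
    return model, subset


def predict_linear(
    model: LinearBaselineClassifier, matrix, subset: GeneSubset | None = None
) -> pd.DataFrame:
    """Predict (call + probabilities) for an expression matrix (RPKM or log scale)."""
    if isinstance(matrix, ExpressionMatrix):
        matrix = matrix if matrix.log_scale else log_transform(matrix)
        frame = matrix.frame
    else:
        frame = np.log2(pd.DataFrame(matrix) + 1.0)
    if subset is not None:
        missing = [g for g in subset.gene_ids if g not in frame.columns]
        if missing:
            raise ValueError(f"{len(missing)} subset genes missing from input")
        frame = frame.loc[:, subset.gene_ids]
    probs = model.predict_proba(frame)
    calls = model.classes_[np.argmax(probs, axis=1)]
    out = pd.DataFrame({"sample_id": frame.index, "call": calls})
    for j, c in enumerate(model.classes_):
        out[f"prob_{c}"] = probs[:, j]
    return out
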