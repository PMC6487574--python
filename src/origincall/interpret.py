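"""Per-class gene importance from trained network connection weights.

Uses connection-weight products (Olden & Jackson): a gene's score for a
class is the sum over all input→hidden→...→output paths of the products of
the weights along the path, i.e. the chained matrix product of the layer
weight matrices. The member's per-gene affine transform is composed into
the first layer (dividing each input row by the gene's fitted scale), so
scores from members with different scalings are on a comparable,
RPKM-referenced footing. Activation nonlinearities are ignored by
construction — the score measures wiring strength, not a local gradient.

Ensemble scores rescale each member's score vector to unit maximum absolute
value and average across members, so no single member dominates by weight
magnitude alone.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .preprocess import LinearTransform

__all__ = ["member_importance", "ensemble_importance", "importance_table"]


def _class_column(mlp: MLPClassifier, class_label: str) -> int:
    classes = [str(c) for c in mlp.classes_]
    if str(class_label) not in classes:
        raise KeyError(f"class {class_label!r} not in model vocabulary")
    return classes.index(str(class_label))


def member_importance(
    member: tuple[LinearTransform, MLPClassifier], class_label: str
) -> np.ndarray:
    """Signed per-gene connection-weight scores of one member for one class.

    For a network with weight matrices W_0 .. W_L the path-product score
    vector for output unit c is ``(diag(1/scale) @ W_0 @ ... @ W_L)[:, c]``.
    A two-class network has a single (logistic) output unit scoring the
    second class; the first class's scores are its negation.
    """
    transform, mlp = member
    product = reduce(np.matmul, mlp.coefs_)  # (n_genes, n_outputs)
    product = product / transform.scale[:, None]
    if mlp.n_outputs_ == 1:
        col = product[:, 0]
        return col if _class_column(mlp, class_label) == 1 else -col
    return product[:, _class_column(mlp, class_label)]


def ensemble_importance(model, class_label: str, top_n: int | None = None) -> pd.DataFrame:
    """Averaged member scores for one class, ranked by absolute magnitude.

    Each member's score vector is rescaled to unit maximum absolute value
    before averaging. Returns a DataFrame with columns
    ``class, rank, gene_id, score`` of length ``min(top_n, n_genes)``;
    rank ties (equal |score|) break lexicographically by gene id.
    """
    scores = []
    for member in model.members_:
        s = member_importance(member, class_label)
        peak = np.abs(s).max()
        scores.append(s / peak if peak > 0 else s)
    mean_score = np.mean(scores, axis=0)
    genes = np.asarray(model.gene_ids_, dtype=object)
    order = np.lexsort((genes.astype(str), -np.abs(mean_score)))
    if top_n is not None:
        order = order[:top_n]
    return pd.DataFrame(
        {
            "class": str(class_label),
            "rank": np.arange(1, len(order) + 1),
            "gene_id": genes[order],
            "score": mean_score[order],
        }
    )


def importance_table(model, top_n: int = 20) -> pd.DataFrame:
    """Top-``top_n`` importance rows for every class in the model."""
    frames = [
        ensemble_importance(model, str(c), top_n=top_n) for c in model.classes_
    ]
    table = pd.concat(frames, ignore_index=True)
    table.attrs["method"] = "olden_connection_weights"
    table.attrs["member_aggregation"] = "unit-max rescaled mean"
    return table
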