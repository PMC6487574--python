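"""Synthetic minority oversampling (SMOTE) for rare-class augmentation.

Each synthetic sample is drawn on the segment between a uniformly chosen
class sample and one of its k nearest same-class neighbors (Euclidean
distance in the feature space supplied, which for ensemble training is the
member's transformed space):

    x_new = x_i + u * (x_nn - x_i),   u ~ Uniform(0, 1)

so synthetic points always lie in the convex hull of their class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = ["OversamplePlan", "build_plan", "smote_oversample", "SmoteOversampler"]


@dataclass
class OversamplePlan:
    """Per-class target sizes for oversampling."""

    targets: dict[str, int] = field(default_factory=dict)
    k_neighbors: int = 5
    seed: int = 0

    def n_new(self, class_label: str, current: int) -> int:
        return max(self.targets.get(class_label, current) - current, 0)


def build_plan(
    class_sizes: Mapping[str, int],
    strategy: str = "to_median",
    k: int = 5,
    seed: int = 0,
    targets: Mapping[str, int] | None = None,
) -> OversamplePlan:
    """Decide per-class target sizes.

    ``to_median`` raises classes below the median class size to the median
    (rounded up); ``to_max`` raises all classes to the largest; ``explicit``
    uses a user map and refuses targets below current size.
    """
    sizes = dict(class_sizes)
    if strategy == "to_median":
        level = int(np.ceil(np.median(list(sizes.values()))))
        plan_targets = {c: max(n, level) for c, n in sizes.items()}
    elif strategy == "to_max":
        level = max(sizes.values())
        plan_targets = {c: level for c in sizes}
    elif strategy == "explicit":
        if targets is None:
            raise ValueError("explicit strategy requires a targets map")
        for c, t in targets.items():
            if c not in sizes:
                raise ValueError(f"target for unknown class {c!r}")
            if t < sizes[c]:
                raise ValueError(
                    f"explicit target {t} for class {c!r} is below its current size {sizes[c]}"
                )
        plan_targets = {c: targets.get(c, n) for c, n in sizes.items()}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return OversamplePlan(targets=plan_targets, k_neighbors=k, seed=seed)


def smote_oversample(
    class_matrix: np.ndarray,
    n_new: int,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate ``n_new`` synthetic samples for one class.

    The effective neighbor count is ``min(k, n - 1)``. A class of size 1
    cannot be interpolated; its single sample is duplicated, with a warning.
    """
    X = np.asarray(class_matrix, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot oversample an empty class")
    if n_new == 0:
        return np.empty((0, X.shape[1]))
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    if n == 1:
        warnings.warn(
            "class of size 1: SMOTE falls back to duplicating the single sample",
            stacklevel=2,
        )
        return np.repeat(X, n_new, axis=0)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    # first neighbor is the point itself
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    seeds = rng.integers(0, n, size=n_new)
    picks = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    base = X[seeds]
    partner = X[neighbor_idx[seeds, picks]]
    return base + u[:, None] * (partner - base)


class SmoteOversampler(BaseEstimator):
    """Resampler raising rare classes to planned target sizes.

    Parameters
    ----------
    k_neighbors : int, default=5
        Neighbors considered per seed point (capped at class size − 1).
    strategy : {"to_median", "to_max", "explicit"}, default="to_median"
    targets : dict, optional
        Explicit per-class targets (``strategy="explicit"``).
    random_state : int, default=0
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        strategy: str = "to_median",
        targets: Mapping[str, int] | None = None,
        random_state: int = 0,
    ):
        self.k_neighbors = k_neighbors
        self.strategy = strategy
        self.targets = targets
        self.random_state = random_state

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) with synthetic samples appended after the originals."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        plan = build_plan(
            dict(zip(classes.tolist(), counts.tolist())),
            strategy=self.strategy,
            k=self.k_neighbors,
            seed=self.random_state,
            targets=self.targets,
        )
        rng = np.random.default_rng(self.random_state)
        new_blocks, new_labels = [], []
        for cls, count in zip(classes, counts):
            n_new = plan.n_new(cls, int(count))
            if n_new == 0:
                continue
            synth = smote_oversample(X[y == cls], n_new, k=self.k_neighbors, seed=rng)
            new_blocks.append(synth)
            new_labels.append(np.full(n_new, cls, dtype=y.dtype))
        if not new_blocks:
            return X, y
        return (
            np.vstack([X] + new_blocks),
            np.concatenate([y] + new_labels),
        )
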