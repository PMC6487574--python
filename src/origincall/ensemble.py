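"""Five-member neural-network ensemble with vote/confidence aggregation.

The classifier trains five feed-forward softmax networks on the same
training cohort, each behind a different per-gene linear scaling of the
log2(RPKM+1) matrix (standardization, min-max, max-abs, robust, and a second
standardized member whose training set is SMOTE-augmented to expand rare
classes). At prediction time each member produces a class-probability
vector; the member's top-voted class is its argmax, the ensemble call is the
modally top-voted class, and the confidence score is the mean of the
winning-class probabilities over the members that top-voted it. A call whose
runner-up class still drew at least ``vote_threshold`` member votes is
flagged as a split call — the signature of mixed-histology samples whose
profile sits between two classes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelBinarizer
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import LabeledCohort, log_transform
from .preprocess import LinearTransform, fit_transform
from .smote import SmoteOversampler

__all__ = [
    "NetworkConfig",
    "PredictionResult",
    "EnsembleOriginClassifier",
    "aggregate_votes",
    "split_call",
    "train_ensemble",
    "predict_cohort",
    "cross_validate_grid",
    "save_ensemble",
    "load_ensemble",
    "DEFAULT_TRANSFORMS",
]

#: per-member linear transform kinds; the last member is SMOTE-augmented
DEFAULT_TRANSFORMS = ("standard", "minmax", "maxabs", "robust", "standard")


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one feed-forward member network."""

    hidden_layer_sizes: tuple[int, ...] = (128,)
    activation: str = "relu"
    max_epochs: int = 200
    learning_rate: float = 1e-3
    l2_penalty: float = 1e-4
    batch_size: int | str = "auto"
    early_stopping_fraction: float = 0.1
    seed: int = 0


@dataclass
class PredictionResult:
    """One sample's ensemble output: member votes and the aggregated call."""

    sample_id: str
    member_probs: np.ndarray  # (n_members, n_classes)
    member_top: list[str]
    call: str
    confidence: float
    vote_count: int
    split: bool
    secondary: str | None
    mean_probs: np.ndarray


def aggregate_votes(
    member_probs: np.ndarray,
    classes: Sequence[str],
    sample_id: str = "",
    confidence_denominator: str = "voters",
    vote_threshold: int = 2,
) -> PredictionResult:
    """Apply the vote/confidence aggregation rule to one sample's member probabilities.

    Each member's top vote is its argmax class; the call is the class
    top-voted most frequently. Modal-vote ties are broken by the larger mean
    probability of the tied class across all members, then by lexicographic
    class code. The confidence score is the mean, over the members whose top
    vote equals the call, of their probability for the call
    (``confidence_denominator="all"`` divides the same sum by the member
    count instead). The runner-up voted class is the secondary call, and the
    prediction is flagged split when it drew at least ``vote_threshold``
    votes.
    """
    probs = np.asarray(member_probs, dtype=float)
    classes = list(classes)
    n_members = probs.shape[0]
    if probs.shape[1] != len(classes):
        raise ValueError("probability matrix width does not match class count")
    sums = probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("member probability vectors must each sum to 1")
    top_idx = probs.argmax(axis=1)
    member_top = [classes[i] for i in top_idx]
    mean_probs = probs.mean(axis=0)

    votes: dict[str, int] = {}
    for c in member_top:
        votes[c] = votes.get(c, 0) + 1
    # order candidates by votes desc, then ensemble-mean probability desc,
    # then lexicographic class code asc
    ranked = sorted(
        votes, key=lambda c: (-votes[c], -mean_probs[classes.index(c)], c)
    )
    call = ranked[0]
    voters = [i for i in range(n_members) if member_top[i] == call]
    call_col = classes.index(call)
    winning_sum = probs[voters, call_col].sum()
    if confidence_denominator == "voters":
        confidence = winning_sum / len(voters)
    elif confidence_denominator == "all":
        confidence = winning_sum / n_members
    else:
        raise ValueError(f"unknown confidence_denominator {confidence_denominator!r}")
    secondary = ranked[1] if len(ranked) > 1 else None
    split = secondary is not None and votes[secondary] >= vote_threshold
    return PredictionResult(
        sample_id=sample_id,
        member_probs=probs,
        member_top=member_top,
        call=call,
        confidence=float(confidence),
        vote_count=len(voters),
        split=split,
        secondary=secondary,
        mean_probs=mean_probs,
    )


def split_call(
    result: PredictionResult, vote_threshold: int = 2
) -> tuple[bool, str | None]:
    """Re-evaluate the split flag of a prediction at a given vote threshold."""
    votes: dict[str, int] = {}
    for c in result.member_top:
        votes[c] = votes.get(c, 0) + 1
    others = {c: v for c, v in votes.items() if c != result.call}
    if not others:
        return False, None
    # deterministic tie-break: most votes, then lexicographic
    secondary = sorted(others, key=lambda c: (-others[c], c))[0]
    return others[secondary] >= vote_threshold, secondary


class EnsembleOriginClassifier(ClassifierMixin, BaseEstimator):
    """Tissue-of-origin classifier: an ensemble of feed-forward networks.

    Expects log2(RPKM+1) expression as input (samples × genes); pass a
    DataFrame to enable gene-id alignment at prediction time. One member
    (``smote_member``) trains on a SMOTE-augmented copy of its transformed
    training matrix so that rare classes contribute more than a handful of
    gradient updates.

    Parameters
    ----------
    transforms : sequence of str, default=("standard","minmax","maxabs","robust","standard")
        Per-member linear transform kinds; the length sets the member count.
    smote_member : int or None, default=4
        Index of the member trained with SMOTE augmentation.
    smote_k : int, default=5
        SMOTE neighbor count.
    smote_strategy : {"to_median","to_max","explicit"}, default="to_median"
    smote_targets : dict, optional
        Explicit per-class target sizes when ``smote_strategy="explicit"``.
    hidden_layer_sizes, activation, max_epochs, learning_rate, l2_penalty,
    batch_size, early_stopping_fraction :
        Shared member-network hyperparameters (see :class:`NetworkConfig`).
    member_configs : sequence of NetworkConfig, optional
        Per-member overrides; must match the member count. Seeds given here
        are used verbatim.
    confidence_denominator : {"voters", "all"}, default="voters"
        Whether the confidence score averages the winning-class
        probabilities over the voting members only or over all members.
    vote_threshold : int, default=2
        Minimum runner-up votes for a split-confidence flag.
    random_state : int, default=0
        Base seed; member i trains with seed ``random_state + i``.
    """

    def __init__(
        self,
        transforms: Sequence[str] = DEFAULT_TRANSFORMS,
        smote_member: int | None = 4,
        smote_k: int = 5,
        smote_strategy: str = "to_median",
        smote_targets: dict | None = None,
        hidden_layer_sizes: tuple[int, ...] = (128,),
        activation: str = "relu",
        max_epochs: int = 200,
        learning_rate: float = 1e-3,
        l2_penalty: float = 1e-4,
        batch_size: int | str = "auto",
        early_stopping_fraction: float = 0.1,
        member_configs: Sequence[NetworkConfig] | None = None,
        confidence_denominator: str = "voters",
        vote_threshold: int = 2,
        random_state: int = 0,
    ):
        self.transforms = transforms
        self.smote_member = smote_member
        self.smote_k = smote_k
        self.smote_strategy = smote_strategy
        self.smote_targets = smote_targets
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.l2_penalty = l2_penalty
        self.batch_size = batch_size
        self.early_stopping_fraction = early_stopping_fraction
        self.member_configs = member_configs
        self.confidence_denominator = confidence_denominator
        self.vote_threshold = vote_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _member_config(self, i: int) -> NetworkConfig:
        if self.member_configs is not None:
            if len(self.member_configs) != len(self.transforms):
                raise ValueError(
                    f"member_configs has length {len(self.member_configs)}, "
                    f"expected {len(self.transforms)}"
                )
            return self.member_configs[i]
        return NetworkConfig(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=self.activation,
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            l2_penalty=self.l2_penalty,
            batch_size=self.batch_size,
            early_stopping_fraction=self.early_stopping_fraction,
            seed=self.random_state + i,
        )

    def _fit_member(
        self, i: int, frame: pd.DataFrame, y: np.ndarray
    ) -> tuple[LinearTransform, MLPClassifier]:
        config = self._member_config(i)
        transform = fit_transform(self.transforms[i], frame)
        Xt = transform.apply(frame)
        yt = y
        if self.smote_member is not None and i == self.smote_member:
            sampler = SmoteOversampler(
                k_neighbors=self.smote_k,
                strategy=self.smote_strategy,
                targets=self.smote_targets,
                random_state=config.seed,
            )
            Xt, yt = sampler.fit_resample(Xt, yt)
        mlp = MLPClassifier(
            hidden_layer_sizes=config.hidden_layer_sizes,
            activation=config.activation,
            solver="adam",
            alpha=config.l2_penalty,
            batch_size=config.batch_size,
            learning_rate_init=config.learning_rate,
            max_iter=config.max_epochs,
            early_stopping=config.early_stopping_fraction > 0,
            validation_fraction=config.early_stopping_fraction or 0.1,
            n_iter_no_change=10,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings are expected
            mlp.fit(Xt, yt)
        if not np.isfinite(mlp.loss_):
            raise RuntimeError(
                f"member {i} training diverged (loss={mlp.loss_}); "
                f"config: {config}"
            )
        return transform, mlp

    def fit(self, X, y):
        """Fit all members on log-scale expression ``X`` and labels ``y``."""
        if len(self.transforms) < 1:
            raise ValueError("at least one member transform is required")
        X_arr, y = validate_data(self, X, y, dtype=float, ensure_min_samples=2)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training requires at least 2 classes")
        gene_names = getattr(self, "feature_names_in_", None)
        if gene_names is None:
            gene_names = np.array([f"f{i}" for i in range(X_arr.shape[1])])
        frame = pd.DataFrame(X_arr, columns=gene_names)
        self.gene_ids_ = list(gene_names)
        self.members_ = [
            self._fit_member(i, frame, np.asarray(y)) for i in range(len(self.transforms))
        ]
        self.manifest_ = {
            "n_members": len(self.members_),
            "transforms": list(self.transforms),
            "smote_member": self.smote_member,
            "classes": [str(c) for c in self.classes_],
            "configs": [asdict(self._member_config(i)) for i in range(len(self.members_))],
            "member_digests": [self.member_digest(i) for i in range(len(self.members_))],
            "data_digest": hashlib.sha256(
                X_arr.tobytes() + np.asarray(y, dtype="U").tobytes()
            ).hexdigest(),
        }
        return self

    def member_digest(self, i: int) -> str:
        """SHA-256 digest of one member's weights (reproducibility check)."""
        check_is_fitted(self, "members_")
        _, mlp = self.members_[i]
        h = hashlib.sha256()
        for w in mlp.coefs_ + mlp.intercepts_:
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()

    # -------------------------------------------------------------- predict

    def _align(self, X, impute_zero: bool):
        """Align a prediction matrix to the training gene set, by gene id."""
        if isinstance(X, pd.DataFrame):
            have = set(X.columns)
            missing = [g for g in self.gene_ids_ if g not in have]
            if missing:
                if not impute_zero:
                    raise ValueError(
                        f"{len(missing)} model genes missing from input "
                        f"(first few: {missing[:5]}); pass impute_zero=True to "
                        f"substitute zeros"
                    )
                X = X.copy()
                for g in missing:
                    X[g] = 0.0
            return X.loc[:, self.gene_ids_]
        return X

    def _member_probabilities(self, frame: pd.DataFrame) -> np.ndarray:
        """(n_members, n_samples, n_classes) member probability tensor."""
        out = np.empty((len(self.members_), len(frame), len(self.classes_)))
        for i, (transform, mlp) in enumerate(self.members_):
            out[i] = mlp.predict_proba(transform.apply(frame))
        return out

    def predict_detail(self, X, impute_zero: bool = False) -> list[PredictionResult]:
        """Full per-sample ensemble output (votes, confidence, split flag)."""
        check_is_fitted(self, "members_")
        X = self._align(X, impute_zero)
        sample_ids = (
            [str(s) for s in X.index]
            if isinstance(X, pd.DataFrame)
            else [str(i) for i in range(len(X))]
        )
        X_arr = validate_data(self, X, dtype=float, reset=False)
        frame = pd.DataFrame(X_arr, columns=self.gene_ids_)
        probs = self._member_probabilities(frame)
        return [
            aggregate_votes(
                probs[:, s, :],
                [str(c) for c in self.classes_],
                sample_id=sample_ids[s],
                confidence_denominator=self.confidence_denominator,
                vote_threshold=self.vote_threshold,
            )
            for s in range(len(frame))
        ]

    def predict(self, X):
        return np.array([r.call for r in self.predict_detail(X)], dtype=object)

    def predict_proba(self, X):
        """Ensemble-mean class probabilities (order of ``classes_``)."""
        check_is_fitted(self, "members_")
        X = self._align(X, impute_zero=False)
        X_arr = validate_data(self, X, dtype=float, reset=False)
        frame = pd.DataFrame(X_arr, columns=self.gene_ids_)
        return self._member_probabilities(frame).mean(axis=0)

    def predict_table(self, X, impute_zero: bool = False) -> pd.DataFrame:
        """Prediction results as a table, one row per sample."""
        results = self.predict_detail(X, impute_zero=impute_zero)
        rows = []
        for r in results:
            row = {
                "sample_id": r.sample_id,
                "call": r.call,
                "confidence": r.confidence,
                "vote_count": r.vote_count,
                "split": r.split,
                "secondary": r.secondary,
            }
            for j, c in enumerate(self.classes_):
                row[f"prob_{c}"] = r.mean_probs[j]
            rows.append(row)
        return pd.DataFrame(rows)


# -------------------------------------------------------- cohort-level API


def train_ensemble(
    train: LabeledCohort,
    transforms: Sequence[str] = DEFAULT_TRANSFORMS,
    smote_member_index: int | None = 4,
    member_configs: Sequence[NetworkConfig] | None = None,
    random_state: int = 0,
    **params,
) -> EnsembleOriginClassifier:
    """Train the ensemble on a labeled cohort (log-transforming RPKM input)."""
    matrix = train.matrix if train.matrix.log_scale else log_transform(train.matrix)
    model = EnsembleOriginClassifier(
        transforms=tuple(transforms),
        smote_member=smote_member_index,
        member_configs=member_configs,
        random_state=random_state,
        **params,
    )
    return model.fit(matrix.frame, train.labels)


def predict_cohort(
    model: EnsembleOriginClassifier, matrix, impute_zero: bool = False
) -> pd.DataFrame:
    """Predict a cohort's expression matrix (RPKM scale; log applied here)."""
    from .io import ExpressionMatrix

    if isinstance(matrix, ExpressionMatrix):
        matrix = matrix if matrix.log_scale else log_transform(matrix)
        frame = matrix.frame
    else:
        frame = np.log2(pd.DataFrame(matrix) + 1.0)
    return model.predict_table(frame, impute_zero=impute_zero)


def cross_validate_grid(
    X,
    y,
    candidates: Sequence[dict],
    estimator: EnsembleOriginClassifier | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Stratified k-fold grid search over candidate parameter sets.

    Classes with fewer samples than ``n_folds`` are pooled into every fold's
    training side (with a warning) rather than split. The winner is the
    candidate with the highest mean fold macro-F1; the full per-candidate
    fold table is returned alongside it.
    """
    if not candidates:
        raise ValueError("no candidate parameter sets given")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    base = estimator if estimator is not None else EnsembleOriginClassifier()
    classes, counts = np.unique(y, return_counts=True)
    rare = set(classes[counts < n_folds])
    if rare:
        warnings.warn(
            f"classes smaller than {n_folds} pooled into every training fold: "
            f"{sorted(map(str, rare))}",
            stacklevel=2,
        )
    rare_mask = np.isin(y, list(rare))
    common_idx = np.flatnonzero(~rare_mask)
    rare_idx = np.flatnonzero(rare_mask)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for ci, params in enumerate(candidates):
        for fold, (tr, te) in enumerate(skf.split(X.iloc[common_idx], y[common_idx])):
            train_idx = np.concatenate([common_idx[tr], rare_idx]).astype(int)
            test_idx = common_idx[te]
            model = clone(base).set_params(**params)
            model.fit(X.iloc[train_idx], y[train_idx])
            pred = model.predict(X.iloc[test_idx])
            score = f1_score(y[test_idx], pred, average="macro", zero_division=0)
            rows.append({"candidate": ci, "fold": fold, "macro_f1": score, **params})
    table = pd.DataFrame(rows)
    means = table.groupby("candidate")["macro_f1"].mean()
    best = dict(candidates[int(means.idxmax())])
    return best, table


# ---------------------------------------------------------- serialization

FORMAT_VERSION = 1


def save_ensemble(model: EnsembleOriginClassifier, directory: str | Path) -> None:
    """Serialize to a directory: a JSON manifest plus one array file per member."""
    check_is_fitted(model, "members_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
            if k != "member_configs"
        },
        "member_configs": [
            asdict(model._member_config(i)) for i in range(len(model.members_))
        ],
        "classes": [str(c) for c in model.classes_],
        "gene_ids": model.gene_ids_,
        "members": [f"member_{i}.npz" for i in range(len(model.members_))],
        "training_manifest": model.manifest_,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for i, (transform, mlp) in enumerate(model.members_):
        arrays = {
            "transform_offset": transform.offset,
            "transform_scale": transform.scale,
            "out_activation": np.array(mlp.out_activation_),
            "n_outputs": np.array(mlp.n_outputs_),
        }
        for j, (w, b) in enumerate(zip(mlp.coefs_, mlp.intercepts_)):
            arrays[f"coef_{j}"] = w
            arrays[f"intercept_{j}"] = b
        np.savez(directory / f"member_{i}.npz", **arrays)


def load_ensemble(directory: str | Path) -> EnsembleOriginClassifier:
    """Load a model saved by :func:`save_ensemble`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {manifest['format_version']}"
        )
    params = dict(manifest["params"])
    for key in ("transforms", "hidden_layer_sizes"):
        if isinstance(params.get(key), list):
            params[key] = tuple(params[key])
    configs = [NetworkConfig(**{**c, "hidden_layer_sizes": tuple(c["hidden_layer_sizes"])})
               for c in manifest["member_configs"]]
    model = EnsembleOriginClassifier(**params)
    model.member_configs = configs
    model.classes_ = np.array(manifest["classes"], dtype=object)
    model.gene_ids_ = list(manifest["gene_ids"])
    model.n_features_in_ = len(model.gene_ids_)
    model.feature_names_in_ = np.array(model.gene_ids_, dtype=object)
    members = []
    for i, fname in enumerate(manifest["members"]):
        with np.load(directory / fname) as data:
            n_layers = sum(1 for k in data.files if k.startswith("coef_"))
            coefs = [data[f"coef_{j}"] for j in range(n_layers)]
            intercepts = [data[f"intercept_{j}"] for j in range(n_layers)]
            config = configs[i]
            mlp = MLPClassifier(
                hidden_layer_sizes=config.hidden_layer_sizes,
                activation=config.activation,
                random_state=config.seed,
            )
            mlp.coefs_ = coefs
            mlp.intercepts_ = intercepts
            mlp.n_layers_ = n_layers + 1
            mlp.n_outputs_ = int(data["n_outputs"])
            mlp.out_activation_ = str(data["out_activation"])
            mlp.classes_ = model.classes_
            mlp.n_features_in_ = len(model.gene_ids_)
            lb = LabelBinarizer()
            lb.fit(model.classes_)
            mlp._label_binarizer = lb
            transform = LinearTransform(
                kind=model.transforms[i] if i < len(model.transforms) else "standard",
                gene_ids=model.gene_ids_,
                offset=data["transform_offset"],
                scale=data["transform_scale"],
            )
            members.append((transform, mlp))
    model.members_ = members
    model.manifest_ = manifest.get("training_manifest", {})
    return model
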