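"""Reading, writing and basic transformation of expression matrices and label tables.

The canonical in-memory orientation is samples × genes. Files may be stored
either way; ``orientation`` says how the file is laid out. Gene and sample
identifiers are opaque strings and are preserved verbatim. Expression values
are RPKM (non-negative reals) unless a log transform has been applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "LabeledCohort",
    "read_expression_matrix",
    "write_expression_matrix",
    "log_transform",
    "inverse_log_transform",
    "read_labels",
    "write_labels",
    "read_gene_list",
    "merge_classes",
]


class ExpressionValidationError(ValueError):
    """Raised when an expression matrix or label table violates its contract."""


@dataclass
class ExpressionMatrix:
    """A samples × genes matrix of non-negative expression values.

    Attributes
    ----------
    frame : pandas.DataFrame
        Rows indexed by sample id, columns by gene id.
    log_scale : bool
        True once :func:`log_transform` has been applied; value
        non-negativity is only enforced on the RPKM scale.
    """

    frame: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.frame.index, self.frame.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate sample identifiers: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ExpressionValidationError(f"duplicate gene identifiers: {dupes}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionValidationError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ExpressionValidationError(
                f"missing value at sample {idx[r]!r}, gene {cols[c]!r}"
            )
        if not self.log_scale and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ExpressionValidationError(
                f"negative expression value at sample {idx[r]!r}, gene {cols[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_genes(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[list(sample_ids)], log_scale=self.log_scale)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.frame.columns]
        if missing:
            raise ExpressionValidationError(
                f"{len(missing)} requested genes absent from matrix "
                f"(first few: {missing[:5]})"
            )
        return ExpressionMatrix(self.frame.loc[:, list(gene_ids)], log_scale=self.log_scale)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: class label plus optional clinical context."""

    sample_id: str
    class_label: str
    is_tumor: bool = True
    organ_system_group: str | None = None
    biopsy_site_class: str | None = None
    tumor_content_pct: float | None = None
    # mixture provenance, set by the simulator for mixed-histology samples
    mixed_with: str | None = None
    mixture_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_content_pct is not None and not (
            0 <= self.tumor_content_pct <= 100
        ):
            raise ExpressionValidationError(
                f"tumor_content_pct for {self.sample_id!r} must lie in [0, 100], "
                f"got {self.tumor_content_pct}"
            )


@dataclass
class LabeledCohort:
    """An expression matrix paired with per-sample metadata and a fixed class vocabulary."""

    matrix: ExpressionMatrix
    metadata: list[SampleMetadata]
    class_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {m.sample_id for m in self.metadata}
        matrix_ids = set(self.matrix.sample_ids)
        if by_id != matrix_ids:
            raise ExpressionValidationError(
                "metadata sample ids do not match expression matrix sample ids"
            )
        if not self.class_vocabulary:
            self.class_vocabulary = sorted({m.class_label for m in self.metadata})
        vocab = set(self.class_vocabulary)
        for m in self.metadata:
            if m.class_label not in vocab:
                raise ExpressionValidationError(
                    f"sample {m.sample_id!r} has label {m.class_label!r} outside "
                    f"the class vocabulary"
                )
        # align metadata order with matrix row order
        order = {m.sample_id: m for m in self.metadata}
        self.metadata = [order[s] for s in self.matrix.sample_ids]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.class_label for m in self.metadata], dtype=object)

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in self.class_vocabulary}
        for m in self.metadata:
            sizes[m.class_label] += 1
        return sizes

    def subset(self, sample_ids: Sequence[str]) -> "LabeledCohort":
        wanted = set(sample_ids)
        return LabeledCohort(
            matrix=self.matrix.subset_samples(list(sample_ids)),
            metadata=[m for m in self.metadata if m.sample_id in wanted],
            class_vocabulary=list(self.class_vocabulary),
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(
    path: str | Path, orientation: str = "samples_by_genes"
) -> ExpressionMatrix:
    """Read a delimited expression file into samples × genes orientation.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text with one header row of identifiers and
        an identifier first column.
    orientation : {"samples_by_genes", "genes_by_samples"}
        Layout of the *file*; the returned matrix is always samples × genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise ExpressionValidationError(
            f"duplicate identifiers in header of {path}: {dupes}"
        )
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionValidationError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if orientation == "genes_by_samples":
        numeric = numeric.T
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as tab-delimited text, samples as rows."""
    matrix.frame.to_csv(path, sep="\t", index_label="sample_id")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1). Zero maps to zero; monotone."""
    if matrix.log_scale:
        raise ExpressionValidationError("matrix is already log-transformed")
    return ExpressionMatrix(np.log2(matrix.frame + 1.0), log_scale=True)


def inverse_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Invert :func:`log_transform`: 2**y − 1, back to the RPKM scale."""
    if not matrix.log_scale:
        raise ExpressionValidationError("matrix is not log-transformed")
    frame = np.exp2(matrix.frame) - 1.0
    return ExpressionMatrix(frame.clip(lower=0.0), log_scale=False)


_LABEL_COLUMNS = {
    "is_tumor",
    "organ_system_group",
    "biopsy_site_class",
    "tumor_content_pct",
    "mixed_with",
    "mixture_fraction",
}


def read_labels(
    path: str | Path, vocabulary: Sequence[str] | None = None
) -> list[SampleMetadata]:
    """Read a sample-label table (columns ``sample_id``, ``class_label``, optional extras)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype={"sample_id": str})
    for col in ("sample_id", "class_label"):
        if col not in df.columns:
            raise ExpressionValidationError(f"label table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ExpressionValidationError(f"duplicate sample ids in label table: {dupes}")
    if vocabulary is not None:
        vocab = set(vocabulary)
        outside = df.loc[~df["class_label"].isin(vocab)]
        if len(outside):
            row = outside.iloc[0]
            raise ExpressionValidationError(
                f"label {row['class_label']!r} of sample {row['sample_id']!r} "
                f"(row {outside.index[0] + 2} of {path}) is outside the vocabulary"
            )
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _LABEL_COLUMNS & set(df.columns):
            value = row[col]
            if pd.isna(value):
                continue
            if col == "is_tumor":
                value = str(value).strip().lower() in ("1", "true", "yes", "t")
            elif col in ("tumor_content_pct", "mixture_fraction"):
                value = float(value)
            kwargs[col] = value
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                class_label=str(row["class_label"]),
                **kwargs,
            )
        )
    return records


def write_labels(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "sample_id": m.sample_id,
                "class_label": m.class_label,
                "is_tumor": int(m.is_tumor),
                "organ_system_group": m.organ_system_group,
                "biopsy_site_class": m.biopsy_site_class,
                "tumor_content_pct": m.tumor_content_pct,
                "mixed_with": m.mixed_with,
                "mixture_fraction": m.mixture_fraction,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line; '#' starts a comment."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    return genes


def merge_classes(cohort: LabeledCohort, merge_map: Mapping[str, str]) -> LabeledCohort:
    """Remap class labels (e.g. combining colon and rectal adenocarcinoma cohorts).

    Every key of ``merge_map`` must be an existing class; targets may be new
    codes or coincide with existing ones (codes are free-form, so a collision
    only triggers a warning).
    """
    vocab = set(cohort.class_vocabulary)
    missing = [c for c in merge_map if c not in vocab]
    if missing:
        raise ExpressionValidationError(f"merge_map references absent classes: {missing}")
    untouched = vocab - set(merge_map)
    for old, new in merge_map.items():
        if new in untouched:
            warnings.warn(
                f"merge target {new!r} collides with an existing class code; "
                f"samples of {old!r} will join it",
                stacklevel=2,
            )
    new_metadata = [
        replace(m, class_label=merge_map.get(m.class_label, m.class_label))
        for m in cohort.metadata
    ]
    new_vocab: list[str] = []
    for c in cohort.class_vocabulary:
        mapped = merge_map.get(c, c)
        if mapped not in new_vocab:
            new_vocab.append(mapped)
    return LabeledCohort(
        matrix=cohort.matrix, metadata=new_metadata, class_vocabulary=new_vocab
    )
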