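"""Synthetic multi-class expression cohorts with planted marker genes.

The generative model is log-normal on the log2 scale: for a sample of class
``c`` and gene ``g``,

    z ~ Normal(base_log_mean + delta * [g in markers(c)], log_sd)
    RPKM = max(2**z - 1, 0)

which matches the log2(x+1) transform used downstream and keeps RPKM values
non-negative. Each class owns a disjoint set of planted marker genes whose
log-mean is shifted upward by ``marker_effect_delta``. Optional paired
"adjacent normal" classes share half of their tumor class's markers (the
tissue-specific half) but lack the tumor-only half, reproducing the
tissue-versus-tumor confusion structure of real cohorts that include
adjacent-normal tissue classes.

Mixed-histology samples and tumor-content dilution are modeled by mixing
class log-means (not samples), giving controllable intermediate profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LabeledCohort, SampleMetadata

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "mix_profiles",
    "dilute_tumor_content",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a small but learnable cohort: 8 balanced classes of 60
    samples over 400 genes with 10 markers per class and a 6 log2-unit marker
    shift against unit log-scale noise — strong, well-separated class signal
    of the kind whole-transcriptome classifiers exploit.
    """

    n_classes: int = 8
    class_sizes: tuple[int, ...] = (60,) * 8
    n_genes: int = 400
    markers_per_class: int = 10
    marker_effect_delta: float = 6.0
    base_log_mean: float = 3.0
    log_sd: float = 1.0
    paired_normals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_sizes) != self.n_classes:
            raise ValueError(
                f"class_sizes has length {len(self.class_sizes)}, expected {self.n_classes}"
            )
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        n_marker_sets = self.n_classes * (2 if self.paired_normals else 1)
        if self.markers_per_class * n_marker_sets > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")
        if self.marker_effect_delta < 0 or self.log_sd <= 0:
            raise ValueError("marker_effect_delta must be >= 0 and log_sd > 0")


@dataclass
class GroundTruth:
    """What was planted: marker sets and per-class log-scale mean vectors."""

    gene_ids: list[str]
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    class_means: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_for(self, class_label: str) -> np.ndarray:
        return self.class_means[class_label]


def _sample_block(
    rng: np.random.Generator, mean: np.ndarray, n: int, log_sd: float
) -> np.ndarray:
    z = rng.normal(loc=mean, scale=log_sd, size=(n, mean.size))
    return np.maximum(np.exp2(z) - 1.0, 0.0)


def generate_cohort(spec: SyntheticSpec) -> tuple[LabeledCohort, GroundTruth]:
    """Draw a labeled cohort and its ground truth, deterministically under ``spec.seed``.

    Tumor classes are named ``C1..Ck``; when ``paired_normals`` is set, each
    tumor class ``Ci`` gets a companion class ``Ci_N`` of the same size whose
    markers are the first half (tissue markers) of ``Ci``'s set plus a
    disjoint normal-only set, and which lacks the second (tumor-only) half.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    truth = GroundTruth(gene_ids=gene_ids)

    classes: list[tuple[str, int, bool]] = []  # (label, size, is_tumor)
    marker_cursor = 0
    m = spec.markers_per_class
    for i in range(spec.n_classes):
        label = f"C{i + 1}"
        markers = gene_ids[marker_cursor : marker_cursor + m]
        marker_cursor += m
        truth.marker_sets[label] = markers
        classes.append((label, spec.class_sizes[i], True))
        if spec.paired_normals:
            normal_label = f"{label}_N"
            tissue_half = markers[: m // 2]
            own = gene_ids[marker_cursor : marker_cursor + m]
            marker_cursor += m
            truth.marker_sets[normal_label] = tissue_half + own[: m - m // 2]
            classes.append((normal_label, spec.class_sizes[i], False))

    for label, _, _ in classes:
        mean = np.full(spec.n_genes, spec.base_log_mean, dtype=float)
        idx = [gene_ids.index(g) for g in truth.marker_sets[label]]
        mean[idx] += spec.marker_effect_delta
        truth.class_means[label] = mean

    blocks, metadata = [], []
    sample_counter = 0
    for label, size, is_tumor in classes:
        blocks.append(_sample_block(rng, truth.class_means[label], size, spec.log_sd))
        for _ in range(size):
            metadata.append(
                SampleMetadata(
                    sample_id=f"S{sample_counter:05d}",
                    class_label=label,
                    is_tumor=is_tumor,
                )
            )
            sample_counter += 1

    frame = pd.DataFrame(
        np.vstack(blocks),
        index=[m_.sample_id for m_ in metadata],
        columns=gene_ids,
    )
    cohort = LabeledCohort(
        matrix=ExpressionMatrix(frame),
        metadata=metadata,
        class_vocabulary=[c[0] for c in classes],
    )
    return cohort, truth


def _mixture_samples(
    truth: GroundTruth,
    class_a: str,
    class_b: str,
    fraction_a: float,
    n: int,
    log_sd: float,
    seed: int,
    id_prefix: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError(f"mixture fraction must lie in [0, 1], got {fraction_a}")
    for c in (class_a, class_b):
        if c not in truth.class_means:
            raise KeyError(f"class {c!r} has no ground-truth mean")
    mean = fraction_a * truth.mean_for(class_a) + (1 - fraction_a) * truth.mean_for(class_b)
    rng = np.random.default_rng(seed)
    values = _sample_block(rng, mean, n, log_sd)
    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    return pd.DataFrame(values, index=ids, columns=truth.gene_ids), mean


def mix_profiles(
    cohort: LabeledCohort,
    truth: GroundTruth,
    class_a: str,
    class_b: str,
    fraction_a: float,
    n: int,
    seed: int,
    log_sd: float = 1.0,
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Mixed-histology samples: per-gene log-mean is the convex mixture of two classes.

    The recorded label is the majority component (``class_a`` when
    ``fraction_a >= 0.5``); the minority class and the mixing fraction are
    kept in the metadata.
    """
    for c in (class_a, class_b):
        if c not in cohort.class_vocabulary:
            raise ValueError(f"class {c!r} not in cohort vocabulary")
    frame, _ = _mixture_samples(
        truth, class_a, class_b, fraction_a, n, log_sd, seed, id_prefix="MIX"
    )
    label, other = (class_a, class_b) if fraction_a >= 0.5 else (class_b, class_a)
    metadata = [
        SampleMetadata(
            sample_id=s,
            class_label=label,
            mixed_with=other,
            mixture_fraction=fraction_a,
        )
        for s in frame.index
    ]
    return ExpressionMatrix(frame), metadata


def dilute_tumor_content(
    cohort: LabeledCohort,
    truth: GroundTruth,
    tumor_class: str,
    background_class: str,
    tumor_fraction: float,
    n: int,
    seed: int,
    log_sd: float = 1.0,
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Tumor profiles diluted by a background (normal) profile.

    Emulates low-tumor-content biopsies: the sample's log-mean profile is
    ``tumor_fraction`` of the tumor class plus the remainder of the
    background class, and ``tumor_content_pct = 100 * tumor_fraction`` is
    recorded. The label stays the tumor class regardless of fraction.
    """
    for c in (tumor_class, background_class):
        if c not in cohort.class_vocabulary:
            raise ValueError(f"class {c!r} not in cohort vocabulary")
    frame, _ = _mixture_samples(
        truth, tumor_class, background_class, tumor_fraction, n, log_sd, seed,
        id_prefix="DIL",
    )
    metadata = [
        SampleMetadata(
            sample_id=s,
            class_label=tumor_class,
            tumor_content_pct=100.0 * tumor_fraction,
        )
        for s in frame.index
    ]
    return ExpressionMatrix(frame), metadata
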