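import numpy as np
import pandas as pd
import pytest

from origincall import (
    EnsembleOriginClassifier,
    SyntheticSpec,
    generate_cohort,
    log_transform,
    stratified_split,
    train_ensemble,
)

#: small-but-learnable settings used by unit tests that need a trained model
TINY_NET = dict(
    hidden_layer_sizes=(16,),
    max_epochs=100,
    early_stopping_fraction=0.0,
    random_state=3,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_classes=4,
        class_sizes=(20,) * 4,
        n_genes=60,
        markers_per_class=5,
        marker_effect_delta=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    cohort, truth = generate_cohort(small_spec)
    return cohort, truth


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = small_cohort
    return stratified_split(cohort, 0.8, seed=11)


@pytest.fixture(scope="session")
def trained_small(small_split):
    train, _ = small_split
    return train_ensemble(train, **TINY_NET)


def expression_frame(matrix):
    """Log-scale frame of an RPKM ExpressionMatrix."""
    return log_transform(matrix).frame


def cohort_truth_labels(cohort, sample_ids):
    by_id = {m.sample_id: m.class_label for m in cohort.metadata}
    return np.array([by_id[s] for s in sample_ids], dtype=object)
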