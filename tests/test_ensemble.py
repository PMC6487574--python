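"""Vote/confidence aggregation, ensemble training, grid search, serialization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from origincall.ensemble import (
    EnsembleOriginClassifier,
    NetworkConfig,
    aggregate_votes,
    cross_validate_grid,
    load_ensemble,
    predict_cohort,
    save_ensemble,
    split_call,
    train_ensemble,
)
from origincall.io import log_transform
from origincall.simulate import SyntheticSpec, generate_cohort
from origincall.preprocess import stratified_split

from conftest import TINY_NET, cohort_truth_labels


class TestAggregationRule:
    def test_unanimous_vote(self):
        probs = np.tile([1.0, 0.0], (5, 1))
        r = aggregate_votes(probs, ["A", "B"])
        assert (r.call, r.confidence, r.vote_count, r.split) == ("A", 1.0, 5, False)
        assert r.secondary is None

    def test_three_two_split_averages_voters_only(self):
        probs = np.array(
            [[0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.4, 0.6], [0.1, 0.9]]
        )
        r = aggregate_votes(probs, ["A", "B"])
        assert r.call == "A"
        assert r.confidence == pytest.approx(np.mean([0.9, 0.8, 0.7]))
        assert r.vote_count == 3
        assert r.secondary == "B"
        assert r.split  # runner-up drew 2 >= 2 votes

    def test_all_members_denominator_option(self):
        probs = np.array(
            [[0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.4, 0.6], [0.1, 0.9]]
        )
        r = aggregate_votes(probs, ["A", "B"], confidence_denominator="all")
        assert r.confidence == pytest.approx((0.9 + 0.8 + 0.7) / 5)

    def test_modal_tie_broken_by_ensemble_mean_probability(self):
        # tops A,A,B,B,C with ensemble-mean P(A)=0.30, P(B)=0.42 -> call B
        probs = np.array(
            [
                [0.5, 0.3, 0.2],
                [0.5, 0.3, 0.2],
                [0.2, 0.6, 0.2],
                [0.2, 0.6, 0.2],
                [0.1, 0.3, 0.6],
            ]
        )
        r = aggregate_votes(probs, ["A", "B", "C"])
        assert r.mean_probs[0] == pytest.approx(0.30)
        assert r.mean_probs[1] == pytest.approx(0.42)
        assert r.call == "B"
        assert r.confidence == pytest.approx(0.6)

    def test_exact_tie_everywhere_breaks_lexicographically(self):
        probs = np.array([[0.6, 0.4], [0.4, 0.6], [0.6, 0.4], [0.4, 0.6]])
        r = aggregate_votes(probs, ["B", "A"])
        assert r.call == "A"

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate_votes(np.array([[0.5, 0.2]]), ["A", "B"])

    @pytest.mark.parametrize(
        "tops,expected_split,expected_secondary",
        [
            (["A"] * 5, False, None),
            (["A", "A", "A", "B", "B"], True, "B"),
            (["A", "A", "A", "A", "B"], False, "B"),
        ],
    )
    def test_split_rule(self, tops, expected_split, expected_secondary):
        classes = ["A", "B"]
        probs = np.array([[0.9, 0.1] if t == "A" else [0.1, 0.9] for t in tops])
        r = aggregate_votes(probs, classes)
        assert (r.split, r.secondary) == (expected_split, expected_secondary)
        assert split_call(r, vote_threshold=2) == (expected_split, expected_secondary)

    def test_confidence_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            raw = rng.uniform(size=(5, 4))
            probs = raw / raw.sum(axis=1, keepdims=True)
            r = aggregate_votes(probs, list("ABCD"))
            assert 0.0 < r.confidence <= 1.0
            assert 1 <= r.vote_count <= 5
            assert r.member_top.count(r.call) == r.vote_count
            # no other class may have strictly more votes than the call
            assert max(r.member_top.count(c) for c in set(r.member_top)) == r.vote_count


class TestTraining:
    def test_training_accuracy_perfect_on_separable_data(self, small_split, trained_small):
        train, _ = small_split
        frame = log_transform(train.matrix).frame
        acc = np.mean(trained_small.predict(frame) == train.labels)
        assert acc == 1.0

    def test_members_agree_on_separable_test_data(self, small_split):
        # unanimity presumes converged members, so train past the point where
        # the quick shared fixture (deliberately small) still underfits
        train, test = small_split
        ensemble = train_ensemble(
            train, hidden_layer_sizes=(64,), max_epochs=600,
            early_stopping_fraction=0.0, random_state=3,
        )
        preds = predict_cohort(ensemble, test.matrix)
        assert (preds["vote_count"] == 5).mean() >= 0.9

    def test_same_seed_gives_identical_weight_digests(self, small_split):
        train, _ = small_split
        a = train_ensemble(train, **TINY_NET)
        b = train_ensemble(train, **TINY_NET)
        assert [a.member_digest(i) for i in range(5)] == [
            b.member_digest(i) for i in range(5)
        ]

    def test_member_digests_differ_across_members(self, trained_small):
        digests = [trained_small.member_digest(i) for i in range(5)]
        assert len(set(digests)) == 5

    def test_no_signal_data_scores_near_chance_on_held_out(self):
        spec = SyntheticSpec(
            n_classes=3, class_sizes=(20,) * 3, n_genes=40,
            markers_per_class=4, marker_effect_delta=0.0, seed=21,
        )
        cohort, _ = generate_cohort(spec)
        train, test = stratified_split(cohort, 0.75, seed=21)
        model = train_ensemble(train, **TINY_NET)
        preds = predict_cohort(model, test.matrix)
        truth = cohort_truth_labels(test, preds["sample_id"])
        assert np.mean(preds["call"].to_numpy() == truth) < 0.67  # chance = 1/3

    def test_member_config_count_must_match(self, small_split):
        train, _ = small_split
        configs = [NetworkConfig()] * 3
        with pytest.raises(ValueError, match="member_configs"):
            train_ensemble(train, member_configs=configs)

    def test_prediction_invariant_to_gene_order(self, small_split, trained_small):
        _, test = small_split
        frame = log_transform(test.matrix).frame
        shuffled = frame.iloc[:, ::-1]
        np.testing.assert_array_equal(
            trained_small.predict(frame), trained_small.predict(shuffled)
        )

    def test_missing_genes_error_and_zero_imputation(self, small_split, trained_small):
        _, test = small_split
        frame = log_transform(test.matrix).frame.drop(columns=["G0000", "G0001"])
        with pytest.raises(ValueError, match="2 model genes missing"):
            trained_small.predict_detail(frame)
        results = trained_small.predict_detail(frame, impute_zero=True)
        assert len(results) == len(frame)

    def test_probability_vectors_sum_to_one(self, small_split, trained_small):
        _, test = small_split
        frame = log_transform(test.matrix).frame
        for r in trained_small.predict_detail(frame):
            np.testing.assert_allclose(r.member_probs.sum(axis=1), 1.0, atol=1e-6)


class TestCrossValidation:
    @pytest.fixture(scope="class")
    @staticmethod
    def xy():
        spec = SyntheticSpec(
            n_classes=3, class_sizes=(15,) * 3, n_genes=30,
            markers_per_class=4, seed=4,
        )
        cohort, _ = generate_cohort(spec)
        return log_transform(cohort.matrix).frame, cohort.labels

    @pytest.fixture(scope="class")
    @staticmethod
    def single_member():
        return EnsembleOriginClassifier(
            transforms=("standard",), smote_member=None,
            hidden_layer_sizes=(16,), max_epochs=80,
            early_stopping_fraction=0.0, random_state=0,
        )

    def test_single_candidate_returned_as_best(self, xy, single_member):
        X, y = xy
        best, table = cross_validate_grid(
            X, y, [{"max_epochs": 40}], estimator=single_member, seed=0
        )
        assert best == {"max_epochs": 40}
        assert len(table) == 5  # one row per fold

    def test_real_config_beats_degenerate_one(self, xy, single_member):
        X, y = xy
        candidates = [
            {"hidden_layer_sizes": (1,), "max_epochs": 1, "learning_rate": 1e-6},
            {"hidden_layer_sizes": (16,), "max_epochs": 80},
        ]
        best, table = cross_validate_grid(
            X, y, candidates, estimator=single_member, seed=0
        )
        assert best == candidates[1]
        means = table.groupby("candidate")["macro_f1"].mean()
        assert means[1] > means[0]

    def test_rare_class_pooled_into_training_folds(self, single_member):
        spec = SyntheticSpec(
            n_classes=3, class_sizes=(12, 12, 3), n_genes=30,
            markers_per_class=4, seed=6,
        )
        cohort, _ = generate_cohort(spec)
        X, y = log_transform(cohort.matrix).frame, cohort.labels
        with pytest.warns(UserWarning, match="pooled into every training fold"):
            _, table = cross_validate_grid(
                X, y, [{"max_epochs": 30}], estimator=single_member, seed=0
            )
        assert len(table) == 5


class TestSerialization:
    def test_save_load_round_trip_predictions(self, small_split, trained_small, tmp_path):
        _, test = small_split
        save_ensemble(trained_small, tmp_path / "model")
        loaded = load_ensemble(tmp_path / "model")
        original = predict_cohort(trained_small, test.matrix)
        restored = predict_cohort(loaded, test.matrix)
        pd.testing.assert_frame_equal(original, restored)

    def test_manifest_versioned(self, trained_small, tmp_path):
        import json

        save_ensemble(trained_small, tmp_path / "model")
        with open(tmp_path / "model" / "manifest.json") as fh:
            manifest = json.load(fh)
        assert manifest["format_version"] == 1
        assert len(manifest["members"]) == 5
        assert manifest["training_manifest"]["data_digest"]
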