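import numpy as np
import pandas as pd
import pytest

from ecpred.benchmark import (
    ClassifierSpec,
    build_benchmark_matrix,
    cross_validate,
    default_classifier_spec,
    external_split,
    external_validate,
    make_folds,
    rf_oob_accuracy,
    tune,
)
from ecpred.descriptors import DescriptorMatrix
from ecpred.synthetic_data import GeneratorConfig, generate_dataset

FAST_RF = ClassifierSpec("rf", {"mtry": ["sqrt"], "n_trees": [100]})
FAST_KNN = ClassifierSpec("knn", {"k": [3]})


@pytest.fixture(scope="module")
def clean_dataset():
    """Near-noiseless conditions: strong signatures, conserved mechanisms."""
    return generate_dataset(GeneratorConfig(
        n_entries=120, signature_strength=1.0, noise_tokens=0.0,
        mechanism_heterogeneity=0.0, seed=5))


class TestFolds:
    def test_equal_division_of_260_into_10(self):
        folds = make_folds([f"E{i}" for i in range(260)], 10, seed=0)
        assert [len(f) for f in folds] == [26] * 10

    def test_sizes_differ_by_at_most_one(self):
        folds = make_folds([f"E{i}" for i in range(47)], 10, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(x for f in folds for x in f) == sorted(f"E{i}" for i in range(47))

    def test_reproducible_from_seed(self):
        ids = [f"E{i}" for i in range(50)]
        assert make_folds(ids, 5, seed=7) == make_folds(ids, 5, seed=7)
        assert make_folds(ids, 5, seed=7) != make_folds(ids, 5, seed=8)

    def test_more_folds_than_entries_rejected(self):
        with pytest.raises(ValueError):
            make_folds([f"E{i}" for i in range(7)], 10, seed=0)

    def test_stratified_option_balances_classes(self):
        ids = [f"E{i}" for i in range(60)]
        labels = [1] * 30 + [2] * 30
        folds = make_folds(ids, 6, seed=0, labels=labels, stratified=True)
        label_of = dict(zip(ids, labels))
        for fold in folds:
            counts = [sum(label_of[i] == c for i in fold) for c in (1, 2)]
            assert abs(counts[0] - counts[1]) <= 1


class TestTuning:
    def test_single_point_grid_returned_directly(self):
        x = np.zeros((10, 3))
        y = np.array([1] * 5 + [2] * 5)
        assert tune(FAST_KNN, x, y) == {"k": 3}

    def test_separating_setting_wins_on_separable_data(self, rng):
        # Two tight, distant clusters: k=1 is perfect, k=39 votes globally
        # with a 60:40 majority and misclassifies the minority class.
        x = np.vstack([rng.normal(0, 0.1, (24, 2)), rng.normal(8, 0.1, (16, 2))])
        y = np.array([1] * 24 + [2] * 16)
        spec = ClassifierSpec("knn", {"k": [39, 1]})
        assert tune(spec, x, y, seed=0) == {"k": 1}

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            tune(FAST_KNN, np.zeros((5, 2)), np.ones(5, dtype=int))

    def test_rf_auto_mtry_expands_with_feature_count(self):
        grid = default_classifier_spec("rf").resolved_grid(100)
        assert grid["mtry"] == [5, 10, 20]


class TestCrossValidation:
    def test_separable_data_predicted_accurately(self, clean_dataset):
        matrix = build_benchmark_matrix(clean_dataset, "overall-bond")
        labels = [e.ec_class for e in clean_dataset]
        result = cross_validate(matrix, labels, FAST_RF, n_folds=10, seed=2)
        assert result.accuracy > 0.9
        assert result.rk > 0.85
        assert result.confusion.total == len(clean_dataset)
        assert sum(result.fold_outcome.correct) == round(
            result.accuracy * len(clean_dataset))

    def test_shuffled_labels_fall_to_chance(self, clean_dataset, rng):
        matrix = build_benchmark_matrix(clean_dataset, "overall-bond")
        labels = np.array([e.ec_class for e in clean_dataset])
        rng.shuffle(labels)
        result = cross_validate(matrix, labels, FAST_RF, n_folds=10, seed=2)
        # Chance level is the largest-class prior (~0.26) plus binomial noise.
        assert result.accuracy < 0.45

    def test_similarity_run_never_sees_test_columns(self, clean_dataset):
        entries = clean_dataset[:40]
        matrix = build_benchmark_matrix(entries, "overall-sim")
        labels = [e.ec_class for e in entries]
        result = cross_validate(matrix, labels, FAST_KNN, n_folds=5, seed=3,
                                is_similarity=True)
        for count, test_ids in zip(result.fold_feature_counts, result.fold_test_ids):
            assert count == len(entries) - len(test_ids)

    def test_fold_models_unchanged_by_removed_test_entry(self, clean_dataset):
        # No-leak spot check: dropping one held-out entry must not change
        # the predictions for the other members of its fold.
        entries = clean_dataset[:40]
        matrix = build_benchmark_matrix(entries, "overall-bond")
        labels = [e.ec_class for e in entries]
        full = cross_validate(matrix, labels, FAST_KNN, n_folds=5, seed=4)
        victim_fold = full.fold_test_ids[0]
        removed = victim_fold[0]
        keep = [i for i in matrix.entry_ids if i != removed]
        label_of = dict(zip(matrix.entry_ids, labels))
        sub = DescriptorMatrix(matrix.df.loc[keep])
        # Re-run manually with the same train split for fold 0.
        from ecpred.benchmark import _make_estimator
        from ecpred.descriptors import zscale_apply, zscale_fit
        train_ids = [i for i in matrix.entry_ids if i not in set(victim_fold)]
        for mat in (matrix, sub):
            params = zscale_fit(mat.rows(train_ids))
            train = zscale_apply(mat.rows(train_ids), params)
            est = _make_estimator("knn", {"k": 3}, 0).fit(
                train.values, np.array([label_of[i] for i in train_ids]))
            rest = [i for i in victim_fold[1:]]
            pred = est.predict(zscale_apply(mat.rows(rest), params).values)
            if mat is matrix:
                expected = pred
            else:
                assert np.array_equal(pred, expected)


class TestDescriptorContrast:
    def test_isomerases_invisible_to_mechanistic_similarity(self):
        # Isomerase mechanisms come from the shared pool, so the class has
        # no mechanistic signature: alignment-based descriptors predict it
        # at chance while overall-reaction similarity recovers it.
        from ecpred.evaluation import per_class_accuracy
        entries = generate_dataset(GeneratorConfig(n_entries=150, seed=42))
        labels = [e.ec_class for e in entries]
        spec = ClassifierSpec("rf", {"mtry": ["sqrt"], "n_trees": [150]})
        acc, recall5 = {}, {}
        for kind in ("overall-sim", "mech-sim"):
            matrix = build_benchmark_matrix(entries, kind)
            r = cross_validate(matrix, labels, spec, n_folds=10, seed=42,
                               is_similarity=True)
            acc[kind] = r.accuracy
            recall5[kind] = per_class_accuracy(r.confusion)[5]
        assert acc["overall-sim"] > acc["mech-sim"]
        assert recall5["mech-sim"] < 0.3
        assert recall5["overall-sim"] > 0.5


class TestRandomForestOOB:
    def test_oob_close_to_cv_on_separable_data(self, clean_dataset):
        matrix = build_benchmark_matrix(clean_dataset, "overall-bond")
        labels = [e.ec_class for e in clean_dataset]
        oob = rf_oob_accuracy(matrix, labels, {"n_trees": 200}, seed=0)
        cv = cross_validate(matrix, labels, FAST_RF, n_folds=10, seed=0).accuracy
        assert abs(oob - cv) < 0.1

    def test_reproducible_from_seed(self, clean_dataset):
        matrix = build_benchmark_matrix(clean_dataset[:60], "overall-bond")
        labels = [e.ec_class for e in clean_dataset[:60]]
        a = rf_oob_accuracy(matrix, labels, {"n_trees": 100}, seed=1)
        b = rf_oob_accuracy(matrix, labels, {"n_trees": 100}, seed=1)
        assert a == b


def _with_ec(entries, codes):
    for e, code in zip(entries, codes):
        e.ec = code
    return entries[:len(codes)]


class TestExternalSplit:
    def test_worked_example_43_test_277_training(self):
        entries = generate_dataset(GeneratorConfig(n_entries=320, seed=13))
        base = entries[:260]
        unique = [f"{i % 6 + 1}.{i // 6 + 1}.{i + 1}" for i in range(43)]
        prefixes = unique + [unique[i % 43] for i in range(17)]
        rng = np.random.default_rng(0)
        rng.shuffle(prefixes)
        new = _with_ec(entries[260:], [f"{p}.1" for p in prefixes])
        split = external_split(base, new)
        assert len(split.test) == 43
        assert len(split.training) == 277
        ec3 = [".".join(e.ec.split(".")[:3]) for e in split.test]
        assert len(set(ec3)) == len(ec3)

    def test_no_duplicates_keeps_all_in_test(self):
        entries = generate_dataset(GeneratorConfig(n_entries=20, seed=1))
        new = _with_ec(entries[10:], [f"{i % 6 + 1}.{i + 1}.1.1" for i in range(10)])
        split = external_split(entries[:10], new)
        assert len(split.test) == 10 and not split.moved

    def test_all_duplicates_empties_test(self):
        entries = generate_dataset(GeneratorConfig(n_entries=12, seed=1))
        new = _with_ec(entries[6:], ["1.1.1.1"] * 3 + ["1.1.1.2"] * 3)
        split = external_split(entries[:6], new, also_dedup_vs_training=False)
        assert len(split.test) == 1  # first occurrence kept, five moved
        new2 = _with_ec(entries[6:], ["1.1.1.1"] * 6)
        base = _with_ec(entries[:6], ["1.1.1.9"] * 6)
        split2 = external_split(base, new2, also_dedup_vs_training=True)
        assert split2.test == []


class TestExternalValidation:
    def test_separable_split_predicted_accurately(self, clean_dataset):
        split = external_split(clean_dataset[:90], clean_dataset[90:])
        result = external_validate(split, "overall-bond", FAST_RF, seed=0)
        assert result["accuracy"] > 0.9

    def test_similarity_columns_span_training_set(self, clean_dataset):
        split = external_split(clean_dataset[:50], clean_dataset[50:70])
        result = external_validate(split, "overall-sim", FAST_KNN, seed=0)
        assert result["n_features"] == len(split.training)

    def test_known_entry_recovered_by_nearest_neighbour(self, clean_dataset):
        import copy
        twin = copy.deepcopy(clean_dataset[0])
        twin.entry_id = "TWIN"  # identical descriptors and EC to entry 0
        split = external_split(clean_dataset[:60], [twin])
        spec = ClassifierSpec("knn", {"k": [1]})
        result = external_validate(split, "overall-bond", spec, seed=0)
        assert result["accuracy"] == 1.0
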