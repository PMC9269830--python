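"""Offline evaluation: fixed splits, sample construction, accuracy grid."""

import numpy as np
import pytest

from eegtw import (EMOTION_ORDER, ClassifierSpec, build_samples, elbn_contrast,
                   evaluate_grid, improvement_argmax, make_classifier,
                   prepare_tw_features, split_sets)
from tests.conftest import make_experiment_tensors


class TestSplitSets:
    def test_ten_sets_with_twelve_three_partition(self):
        sets = split_sets()
        assert [s.set_id for s in sets] == list(range(1, 11))
        for s in sets:
            assert len(s.train_trials) == 12 and len(s.test_trials) == 3
            assert set(s.train_trials) | set(s.test_trials) <= set(range(15))

    def test_set_one_verbatim(self):
        s = split_sets()[0]
        assert s.test_trials == (3, 7, 8)
        assert s.train_trials == (0, 1, 2, 4, 5, 6, 9, 10, 11, 12, 13, 14)

    def test_set_one_test_covers_all_classes(self):
        assert sorted(split_sets()[0].test_labels()) == [-1, 0, 1]

    def test_set_three_overlap_preserved(self):
        s = split_sets()[2]
        assert set(s.train_trials) & set(s.test_trials) == {12}

    def test_every_test_fold_is_class_balanced(self):
        for s in split_sets():
            assert sorted(EMOTION_ORDER[i] for i in s.test_trials) == [-1, 0, 1]


class TestSamples:
    def test_sample_dimensions_follow_tw(self, two_experiments):
        for tw, dim in ((180, 290), (2, 26100)):
            X, y, meta = build_samples(
                prepare_tw_features(two_experiments, tw))
            assert X.shape == (30, dim)
            assert set(y) == {-1, 0, 1}
            assert meta.shape[0] == 30

    def test_single_experiment_gives_fifteen_samples(self, rng):
        tensors = make_experiment_tensors(rng)
        X, _, _ = build_samples(prepare_tw_features(tensors, 180))
        assert X.shape[0] == 15

    def test_mixed_tw_rejected(self, two_experiments):
        a = prepare_tw_features(two_experiments, 180)
        b = prepare_tw_features(two_experiments, 90)
        with pytest.raises(ValueError, match="mix"):
            build_samples(a + b[:1])

    def test_flattening_order_channel_band_window(self, rng):
        tensors = prepare_tw_features(make_experiment_tensors(rng), 90)
        X, _, _ = build_samples(tensors)
        v = tensors[0].values
        assert X[0, 0] == v[0, 0, 0]
        assert X[0, 1] == v[0, 0, 1]       # window fastest
        assert X[0, 2] == v[0, 1, 0]       # then band
        assert X[0, 10] == v[1, 0, 0]      # then channel


class TestClassifiers:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_classifier("RandomForest")

    def test_overrides_applied(self):
        clf = ClassifierSpec("Bagging", {"n_estimators": 7}).build()
        assert clf.n_estimators == 7

    def test_canonical_defaults(self):
        knn = make_classifier("KNN")
        assert knn.n_neighbors == 5 and knn.p == 2
        mlp = make_classifier("MLP")
        assert mlp.hidden_layer_sizes == (100, 3) and mlp.solver == "lbfgs"
        bag = make_classifier("Bagging")
        assert bag.n_estimators == 500


@pytest.fixture(scope="module")
def tensors():
    rng = np.random.default_rng(77)
    return (make_experiment_tensors(rng, 0, 0, separation=2.0) +
            make_experiment_tensors(rng, 1, 0, separation=2.0))


class TestGrid:
    def test_separable_data_classified_correctly(self, tensors):
        res = evaluate_grid(tensors, tw_lengths=[180],
                            classifiers=[ClassifierSpec("LR")])
        assert float(res.mean_table.iloc[0, 0]) > 90.0

    def test_grid_shape_and_bounds(self, tensors):
        res = evaluate_grid(tensors, tw_lengths=[180, 90],
                            classifiers=[ClassifierSpec("LR"),
                                         ClassifierSpec("GNB")])
        assert res.mean_table.shape == (2, 2)
        assert res.per_set.shape[0] == 2 * 2 * 10
        assert ((res.per_set["accuracy"] >= 0)
                & (res.per_set["accuracy"] <= 1)).all()

    def test_accuracy_invariant_to_tensor_order(self, tensors):
        res1 = evaluate_grid(tensors, tw_lengths=[180],
                             classifiers=[ClassifierSpec("LR")])
        shuffled = list(tensors)[::-1]
        res2 = evaluate_grid(shuffled, tw_lengths=[180],
                             classifiers=[ClassifierSpec("LR")])
        np.testing.assert_array_equal(res1.per_set["accuracy"],
                                      res2.per_set["accuracy"])

    def test_elbn_makes_accuracy_scale_invariant(self, tensors):
        """Multiplying one experiment's features by a positive constant
        changes no accuracy once ELBN is on."""
        import copy
        res_ref = evaluate_grid(tensors, tw_lengths=[180],
                                classifiers=[ClassifierSpec("LR")], elbn_on=True)
        distorted = copy.deepcopy(list(tensors))
        for t in distorted:
            if (t.subject_id, t.experiment_id) == (0, 0):
                t.values = t.values * 5.0
        res_d = evaluate_grid(distorted, tw_lengths=[180],
                              classifiers=[ClassifierSpec("LR")], elbn_on=True)
        np.testing.assert_array_equal(res_ref.per_set["accuracy"],
                                      res_d.per_set["accuracy"])

    def test_confusion_matrices_consistent(self, tensors):
        res = evaluate_grid(tensors, tw_lengths=[180],
                            classifiers=[ClassifierSpec("GNB")])
        cm = res.confusions[(180, "GNB", 1)]
        assert cm.shape == (3, 3) and cm.sum() == 6  # 3 test trials x 2 exps


class TestContrast:
    def test_identical_tables_give_zero(self, rng):
        tensors = make_experiment_tensors(rng)
        res = evaluate_grid(tensors, tw_lengths=[180],
                            classifiers=[ClassifierSpec("GNB")])
        diff = elbn_contrast(res.mean_table, res.mean_table)
        assert (diff.to_numpy() == 0).all()

    def test_argmax_reports_peak_cell(self):
        import pandas as pd
        a = pd.DataFrame({"LR": [50.0, 60.0]}, index=[180, 2])
        b = pd.DataFrame({"LR": [55.0, 81.63]}, index=[180, 2])
        tw, clf, val = improvement_argmax(elbn_contrast(a, b))
        assert (tw, clf) == (2, "LR")
        assert val == pytest.approx(21.63)

    def test_shape_mismatch_rejected(self):
        import pandas as pd
        a = pd.DataFrame({"LR": [1.0]})
        b = pd.DataFrame({"LR": [1.0, 2.0]})
        with pytest.raises(ValueError):
            elbn_contrast(a, b)
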