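import numpy as np
import pandas as pd
import pytest

from vrmotion.classify import (
    MovementClassificationModel,
    kfold_evaluate,
    oob_importance,
    predict,
    train,
)
from vrmotion.features import FeatureSpec, WindowDataset


def _dataset(X, y):
    return WindowDataset(
        features=pd.DataFrame(
            X, columns=[f"f{i}" for i in range(np.asarray(X).shape[1])]
        ),
        labels=np.asarray(y, dtype=object),
        starts=np.arange(len(y)),
        spec=FeatureSpec(),
    )


@pytest.fixture
def separable(rng):
    """Two well-separated Gaussian blobs in two features."""
    n = 100
    X = np.vstack(
        [rng.normal(0, 0.3, (n, 2)), rng.normal(4, 0.3, (n, 2))]
    )
    y = ["a"] * n + ["b"] * n
    return _dataset(X, y)


class TestTrainPredict:
    def test_separable_data_perfect_training_accuracy(self, separable):
        model = train(separable, n_trees=10, seed=0)
        pred, _ = predict(model, separable.features.to_numpy())
        assert np.mean(pred == separable.labels) == 1.0

    def test_single_full_tree_matches_hand_built_partition(self):
        """One unbootstrapped full-depth tree reproduces the exact rule a
        hand-built CART finds on an axis-separable 8-point set."""
        X = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [5, 0], [5, 1], [6, 0], [6, 1]],
            dtype=float,
        )
        y = ["lo"] * 4 + ["hi"] * 4
        ds = _dataset(X, y)
        model = train(ds, n_trees=1, seed=0, bootstrap=False)
        # the only impurity-clearing split is f0 < ~3: probe both sides
        probe = np.array([[2.9, 0.5], [3.1, 0.5], [-1, 0], [9, 1]])
        pred, _ = predict(model, probe)
        assert list(pred) == ["lo", "hi", "lo", "hi"]

    def test_same_seed_reproduces_predictions(self, separable):
        a = train(separable, n_trees=20, seed=7)
        b = train(separable, n_trees=20, seed=7)
        X = separable.features.to_numpy()
        assert np.array_equal(predict(a, X)[0], predict(b, X)[0])
        assert all(
            np.array_equal(sa, sb)
            for sa, sb in zip(a.bootstrap_indices(), b.bootstrap_indices())
        )

    def test_majority_vote_matches_hand_count(self, separable):
        model = train(separable, n_trees=15, seed=3)
        X = separable.features.to_numpy()[:10]
        tree_preds = model.tree_predictions(X)
        pred, votes = predict(model, X)
        for i in range(10):
            counts = {c: (tree_preds[:, i] == c).sum() for c in model.classes}
            assert votes.iloc[i].to_dict() == counts
            assert counts[pred[i]] == max(counts.values())

    def test_tie_breaks_to_first_class_in_order(self):
        """With 2 disagreeing trees the earlier class name wins."""
        X = np.array([[0.0], [1.0]] * 8)
        y = ["a", "b"] * 8
        ds = _dataset(X, y)
        model = train(ds, n_trees=2, seed=1, bootstrap=False, max_depth=1)
        pred, votes = predict(model, np.array([[0.5]]))
        row = votes.iloc[0]
        if row["a"] == row["b"]:
            assert pred[0] == "a"

    def test_single_class_data_warns(self):
        ds = _dataset(np.random.default_rng(0).normal(size=(20, 2)), ["a"] * 20)
        with pytest.warns(UserWarning):
            model = train(ds, n_trees=3, seed=0)
        pred, _ = predict(model, ds.features.to_numpy())
        assert set(pred) == {"a"}


class TestCrossValidation:
    def test_separable_classes_near_perfect(self, separable):
        report = kfold_evaluate(separable, k=5, seed=0, n_trees=10)
        assert report.accuracy > 0.98
        assert report.confusion.to_numpy().sum() == len(separable)

    def test_fold_sizes_balanced(self, separable):
        report = kfold_evaluate(separable, k=5, seed=0, n_trees=5)
        sizes = np.bincount(report.fold_assignments)
        assert list(sizes) == [40] * 5

    def test_shuffled_labels_fall_to_chance(self, rng):
        """Chance-level oracle: balanced C-class data with permuted labels
        scores about 1/C out of fold."""
        n, c = 150, 3
        X = rng.normal(size=(n * c, 5))
        y = np.array([f"c{i}" for i in range(c) for _ in range(n)], dtype=object)
        rng.shuffle(y)
        report = kfold_evaluate(_dataset(X, y), k=5, seed=0, n_trees=20)
        assert abs(report.accuracy - 1 / c) < 0.1

    def test_confusion_rows_sum_to_support(self, separable):
        report = kfold_evaluate(separable, k=4, seed=1, n_trees=5)
        y = np.asarray(separable.labels)
        for cls in report.confusion.index:
            assert report.confusion.loc[cls].sum() == (y == cls).sum()
        assert np.isclose(
            report.accuracy,
            np.trace(report.confusion.to_numpy()) / len(y),
        )


class TestOutOfBag:
    def test_oob_fraction_near_e_inverse(self, separable):
        model = train(separable, n_trees=100, seed=0)
        n = len(separable)
        fractions = [len(oob) / n for oob in model.oob_indices(n)]
        assert abs(np.mean(fractions) - np.exp(-1)) < 0.03

    def test_noise_feature_has_negligible_importance(self, rng):
        n = 150
        informative = np.concatenate([rng.normal(0, 0.3, n), rng.normal(4, 0.3, n)])
        noise = rng.normal(size=2 * n)
        X = np.stack([informative, noise], axis=1)
        y = ["a"] * n + ["b"] * n
        ds = _dataset(X, y)
        model = train(ds, n_trees=40, seed=0)
        imp = oob_importance(model, ds).importance
        assert imp["f0"] > 10 * max(imp["f1"], 1e-6)
        assert abs(imp["f1"]) < 0.05 * model.n_trees / 100 * 40

    def test_duplicated_feature_splits_importance(self, rng):
        n = 120
        informative = np.concatenate([rng.normal(0, 0.5, n), rng.normal(3, 0.5, n)])
        X = np.stack([informative, informative.copy()], axis=1)
        y = ["a"] * n + ["b"] * n
        ds = _dataset(X, y)
        model = train(ds, n_trees=40, seed=0)
        imp = oob_importance(model, ds).importance
        # a duplicated predictor backs the other one up: each permutation
        # alone barely hurts, so neither copy dominates
        single = _dataset(X[:, :1], y)
        solo = train(single, n_trees=40, seed=0)
        solo_imp = oob_importance(solo, single).importance["f0"]
        assert imp.max() < solo_imp


class TestModelResultsApi:
    def test_fit_summary_reports_accuracy_and_importance(self, separable):
        results = MovementClassificationModel(separable, n_trees=10, k=4).fit(seed=0)
        text = results.summary()
        assert "CV accuracy" in text and "importances" in text
        assert results.report.accuracy > 0.95

    def test_ensemble_beats_majority_class_baseline(self, window_dataset):
        import pandas as pd

        sub_idx = np.arange(0, len(window_dataset), 10)
        ds = WindowDataset(
            features=window_dataset.features.iloc[sub_idx].reset_index(drop=True),
            labels=np.asarray(window_dataset.labels)[sub_idx],
            starts=window_dataset.starts[sub_idx],
            spec=window_dataset.spec,
        )
        model = train(ds, n_trees=20, seed=0)
        pred, _ = predict(model, ds.features.to_numpy())
        train_acc = np.mean(pred == ds.labels)
        baseline = pd.Series(ds.labels).value_counts(normalize=True).max()
        assert train_acc >= baseline
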