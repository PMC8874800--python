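"""Bagged decision-tree classification of movement windows.

A bagged-trees ensemble trains each decision tree on a bootstrap resample
(with replacement, same size as the training set) and predicts by simple
majority vote over the trees, with a deterministic tie-break toward the
first class in canonical (sorted) order.  All features are candidates at
every split.  Per-tree out-of-bag (OOB) samples — the training rows absent
from a tree's bootstrap — support permutation feature importance: the
increase in a tree's OOB error when one feature's OOB values are shuffled,
summed over trees.

Tree growing and bootstrap bookkeeping are delegated to scikit-learn
(``BaggingClassifier`` over ``DecisionTreeClassifier``); voting, OOB
importance and cross-validated evaluation are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import WindowDataset

__all__ = [
    "BaggedTreesModel",
    "EvaluationReport",
    "ImportanceReport",
    "train",
    "predict",
    "kfold_evaluate",
    "oob_importance",
    "MovementClassificationModel",
    "MovementClassificationResults",
]

DEFAULT_N_TREES = 100


@dataclass
class BaggedTreesModel:
    """A fitted bagged-trees ensemble with its bootstrap bookkeeping."""

    ensemble: BaggingClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    seed: int
    n_trees: int

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_samples) array of per-tree class predictions."""
        X = np.asarray(X, float)
        preds = [est.predict(X[:, feats]) for est, feats in zip(
            self.ensemble.estimators_, self.ensemble.estimators_features_
        )]
        cls = np.asarray(self.ensemble.classes_)
        return np.stack([cls[p.astype(int)] if p.dtype.kind != "O" else p for p in preds])

    def bootstrap_indices(self) -> list[np.ndarray]:
        return [np.asarray(s) for s in self.ensemble.estimators_samples_]

    def oob_indices(self, n_samples: int) -> list[np.ndarray]:
        """Per-tree out-of-bag index sets (complement of bootstrap support)."""
        out = []
        for sample in self.bootstrap_indices():
            mask = np.ones(n_samples, dtype=bool)
            mask[sample] = False
            out.append(np.flatnonzero(mask))
        return out


@dataclass
class EvaluationReport:
    """Cross-validated accuracy, per-class true-positive rates, confusion."""

    accuracy: float
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    per_class_tpr: pd.Series
    fold_assignments: np.ndarray

    def normalized_confusion(self) -> pd.DataFrame:
        return self.confusion.div(self.confusion.sum(axis=1), axis=0)


@dataclass
class ImportanceReport:
    """Per-feature OOB permutation importance (summed error increase)."""

    importance: pd.Series  # indexed by feature name, descending not enforced

    def ranked(self) -> pd.Series:
        return self.importance.sort_values(ascending=False)


def train(
    dataset: WindowDataset,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    max_features=None,
    bootstrap: bool = True,
) -> BaggedTreesModel:
    """Fit a bagged-trees ensemble on a window dataset.

    Deterministic for a given seed.  ``max_features=None`` considers all
    features at every split (the bagging default); Gini impurity splits;
    trees grown to purity unless ``max_depth``/``min_samples_leaf`` say
    otherwise.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(dataset.labels, dtype=object)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        warnings.warn("single-class training data; model is degenerate", stacklevel=2)
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,
        random_state=seed,
    )
    ensemble = BaggingClassifier(
        estimator=tree,
        n_estimators=n_trees,
        max_samples=1.0,
        bootstrap=bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    ensemble.fit(dataset.features.to_numpy(float), y)
    return BaggedTreesModel(
        ensemble=ensemble,
        classes=classes,
        feature_names=tuple(dataset.features.columns),
        seed=seed,
        n_trees=n_trees,
    )


def predict(model: BaggedTreesModel, X) -> tuple[np.ndarray, pd.DataFrame]:
    """Majority-vote class per row, plus the per-class vote distribution.

    Vote ties break toward the first class in the model's canonical
    (sorted) class order.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    tree_preds = model.tree_predictions(X)
    votes = pd.DataFrame(
        {c: (tree_preds == c).sum(axis=0) for c in model.classes}
    )
    # idxmax returns the first column on ties -> canonical-order tie-break
    winners = votes.idxmax(axis=1).to_numpy(dtype=object)
    return winners, votes


def kfold_evaluate(
    dataset: WindowDataset,
    k: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    **tree_params,
) -> EvaluationReport:
    """Stratified K-fold cross-validation with pooled out-of-fold predictions.

    Folds are stratified by class and shuffled with the run seed; the
    pooled predictions give the overall accuracy, the confusion matrix
    (rows sum to class support) and per-class true-positive rates.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(dataset.labels, dtype=object)
    if len(y) < k:
        raise ValueError("dataset smaller than the number of folds")
    X = dataset.features
    classes = sorted(set(y))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    predictions = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        sub = WindowDataset(
            features=X.iloc[train_idx].reset_index(drop=True),
            labels=y[train_idx],
            starts=dataset.starts[train_idx],
            spec=dataset.spec,
        )
        model = train(sub, n_trees=n_trees, seed=seed + fold, **tree_params)
        predictions[test_idx], _ = predict(model, X.iloc[test_idx].to_numpy(float))
        fold_of[test_idx] = fold
    accuracy = float(np.mean(predictions == y))
    confusion = pd.DataFrame(
        _sk_confusion(y, predictions, labels=classes), index=classes, columns=classes
    )
    support = confusion.sum(axis=1)
    tpr = pd.Series(np.diag(confusion) / support.replace(0, np.nan), index=classes)
    return EvaluationReport(accuracy, confusion, tpr, fold_of)


def oob_importance(
    model: BaggedTreesModel, dataset: WindowDataset, seed: int | None = None
) -> ImportanceReport:
    """Permutation importance on each tree's out-of-bag samples.

    For every tree: compute its OOB misclassification error, then for each
    feature shuffle that feature's values among the OOB rows and record
    the error increase.  Importances are the increases summed over trees
    (so they grow with ensemble size); positive values mean the feature
    carried information.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    X = dataset.features.to_numpy(float)
    y = np.asarray(dataset.labels, dtype=object)
    n = len(y)
    totals = np.zeros(len(model.feature_names))
    cls = np.asarray(model.ensemble.classes_)
    for est, oob in zip(model.ensemble.estimators_, model.oob_indices(n)):
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]

        def _decode(p):
            return p if p.dtype.kind == "O" else cls[p.astype(int)]

        base_err = np.mean(_decode(est.predict(X_oob)) != y_oob)
        for j in range(X.shape[1]):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            totals[j] += np.mean(_decode(est.predict(X_perm)) != y_oob) - base_err
    return ImportanceReport(pd.Series(totals, index=model.feature_names))


class MovementClassificationModel:
    """Statsmodels-style front end: window dataset in, fitted results out.

    Parameters
    ----------
    dataset : WindowDataset
        21-feature windows with mode-derived class labels.
    n_trees : int
        Ensemble size (default 100).
    k : int
        Cross-validation folds (default 5).
    """

    def __init__(
        self,
        dataset: WindowDataset,
        n_trees: int = DEFAULT_N_TREES,
        k: int = 5,
        **tree_params,
    ):
        self.dataset = dataset
        self.n_trees = n_trees
        self.k = k
        self.tree_params = tree_params

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str = "label", **kw):
        """Build from a flat table whose non-label columns are features."""
        feature_cols = [c for c in frame.columns if c not in (label_column, "start")]
        from .features import FeatureSpec

        dataset = WindowDataset(
            features=frame[feature_cols].reset_index(drop=True),
            labels=frame[label_column].to_numpy(object),
            starts=frame["start"].to_numpy() if "start" in frame else np.arange(len(frame)),
            spec=FeatureSpec(),
        )
        return cls(dataset, **kw)

    def fit(self, seed: int = 0, evaluate: bool = True, importance: bool = True):
        model = train(
            self.dataset, n_trees=self.n_trees, seed=seed, **self.tree_params
        )
        report = (
            kfold_evaluate(
                self.dataset, k=self.k, seed=seed, n_trees=self.n_trees,
                **self.tree_params,
            )
            if evaluate
            else None
        )
        imp = oob_importance(model, self.dataset) if importance else None
        return MovementClassificationResults(self, model, report, imp, seed)


class MovementClassificationResults:
    """Fitted ensemble plus its cross-validated evaluation and importances."""

    def __init__(self, model_spec, model, report, importance, seed):
        self.model_spec = model_spec
        self.model: BaggedTreesModel = model
        self.report: EvaluationReport | None = report
        self.importance: ImportanceReport | None = importance
        self.seed = seed

    def predict(self, X):
        winners, _ = predict(self.model, X)
        return winners

    def summary(self) -> str:
        lines = ["Bagged-trees movement classification", "=" * 40]
        lines.append(
            f"windows: {len(self.model_spec.dataset)}; features: "
            f"{len(self.model.feature_names)}; trees: {self.model.n_trees}; "
            f"seed: {self.seed}"
        )
        if self.report is not None:
            lines.append(
                f"{self.model_spec.k}-fold CV accuracy: {self.report.accuracy:.4f}"
            )
            lines.append("per-class true-positive rates:")
            for c, v in self.report.per_class_tpr.items():
                lines.append(f"  {c:>12}: {v:.4f}")
        if self.importance is not None:
            top = self.importance.ranked().head(5)
            lines.append("top OOB permutation importances:")
            for name, v in top.items():
                lines.append(f"  {name:>24}: {v:.4f}")
        return "\n".join(lines)
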