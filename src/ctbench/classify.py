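"""Uniform fit/predict harness over five standard classifier families.

The harness trains cell-type classifiers on a log-normalised expression
matrix restricted to a feature set, in either of two multiclass strategies:

* ``multiclass`` — the backend handles all classes jointly (multinomial
  logistic regression, multiclass SVM/forest/network/boosting);
* ``one_vs_all`` — one binary backend per class, fitted on 1-vs-rest
  relabeled data; the composite predicts by argmax over per-class
  confidence (calibrated probability when the backend exposes one,
  otherwise the decision value), ties broken by class order.

Backends are established implementations (scikit-learn, LightGBM) reached
only through this module's contract; swapping a backend changes no pipeline
code.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .containers import LogNormalizedMatrix

log = logging.getLogger(__name__)

MULTICLASS = "multiclass"
ONE_VS_ALL = "one_vs_all"


def _make_logistic_regression(params: dict, seed: int):
    from sklearn.linear_model import LogisticRegression

    defaults = {"max_iter": 500}
    return LogisticRegression(random_state=seed, **{**defaults, **params})


def _make_svm(params: dict, seed: int):
    from sklearn.svm import SVC

    return SVC(random_state=seed, **params)


def _make_random_forest(params: dict, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(random_state=seed, **params)


def _make_neural_network(params: dict, seed: int):
    from sklearn.neural_network import MLPClassifier

    # >= 3 hidden layers of 100 ReLU neurons trained by Adam, with a small
    # fixed iteration budget; all of it overridable through the spec.
    defaults = {
        "hidden_layer_sizes": (100, 100, 100),
        "activation": "relu",
        "solver": "adam",
        "max_iter": 50,
    }
    return MLPClassifier(random_state=seed, **{**defaults, **params})


def _make_gradient_boosted_trees(params: dict, seed: int):
    from lightgbm import LGBMClassifier

    defaults = {"verbose": -1, "n_estimators": 100}
    return LGBMClassifier(random_state=seed, **{**defaults, **params})


@dataclass
class _Family:
    name: str
    builder: Callable[[dict, int], object]
    modes: tuple
    allowed_params: frozenset


_FAMILIES: dict = {}


def register_family(name, builder, modes=(MULTICLASS,), allowed_params=()):
    """Register a classifier family (used by tests to plug stub backends)."""
    _FAMILIES[name] = _Family(name, builder, tuple(modes), frozenset(allowed_params))


register_family(
    "logistic_regression",
    _make_logistic_regression,
    modes=(MULTICLASS, ONE_VS_ALL),
    allowed_params={"penalty", "solver", "max_iter", "C", "tol", "l1_ratio", "n_jobs"},
)
register_family(
    "svm",
    _make_svm,
    modes=(MULTICLASS,),
    allowed_params={"kernel", "C", "gamma", "degree", "tol", "probability"},
)
register_family(
    "random_forest",
    _make_random_forest,
    modes=(MULTICLASS, ONE_VS_ALL),
    allowed_params={"n_estimators", "max_depth", "max_features", "min_samples_leaf", "n_jobs"},
)
register_family(
    "neural_network",
    _make_neural_network,
    modes=(MULTICLASS,),
    allowed_params={
        "hidden_layer_sizes", "activation", "solver", "alpha", "max_iter",
        "batch_size", "learning_rate_init", "early_stopping", "tol",
    },
)
register_family(
    "gradient_boosted_trees",
    _make_gradient_boosted_trees,
    modes=(MULTICLASS,),
    allowed_params={
        "num_leaves", "max_bin", "min_data_in_leaf", "lambda_l2", "extra_trees",
        "path_smooth", "n_estimators", "learning_rate", "min_child_samples", "reg_lambda",
    },
)


@dataclass
class ClassifierSpec:
    """A classifier family + strategy + hyperparameters + seed."""

    family: str
    mode: str = MULTICLASS
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; known: {sorted(_FAMILIES)}"
            )
        fam = _FAMILIES[self.family]
        if self.mode not in fam.modes:
            raise ValueError(
                f"family {self.family!r} supports modes {fam.modes}, not {self.mode!r}"
            )
        unknown = set(self.hyperparameters) - fam.allowed_params
        if unknown:
            raise ValueError(
                f"hyperparameter(s) {sorted(unknown)} are not legal for family "
                f"{self.family!r}; allowed: {sorted(fam.allowed_params)}"
            )

    def build_backend(self):
        return _FAMILIES[self.family].builder(dict(self.hyperparameters), int(self.seed))


@dataclass
class HyperparameterGrid:
    """Per-parameter candidate lists, enumerated odometer-style.

    Parameters iterate in declaration order with values in listed order; the
    last-declared parameter varies fastest. The enumeration order is the
    grid-search tie-breaking order.
    """

    params: dict

    def __len__(self) -> int:
        out = 1
        for v in self.params.values():
            out *= len(v)
        return out

    def enumerate(self):
        if not self.params:
            yield {}
            return
        names = list(self.params)
        for combo in itertools.product(*(self.params[n] for n in names)):
            yield dict(zip(names, combo))


@dataclass
class FittedModel:
    """A fitted backend plus everything needed to apply it safely."""

    backend: object
    spec: ClassifierSpec
    feature_ids: np.ndarray
    class_names: np.ndarray
    confidence_sources: Optional[dict] = None  # one_vs_all only

    def predict(self, X: LogNormalizedMatrix, y_true=None) -> "PredictionSet":
        return predict(self, X, y_true)


@dataclass
class PredictionSet:
    """Per-cell true and predicted labels, both drawn from class_names."""

    cell_ids: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    class_names: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.cell_ids) == len(self.true_labels) == len(self.predicted_labels)):
            raise ValueError("cell_ids, true_labels and predicted_labels must align")


class _OneVsAllComposite:
    """One binary backend per class; argmax over per-class confidence."""

    def __init__(self, spec: ClassifierSpec, class_names: np.ndarray):
        self.spec = spec
        self.class_names = class_names
        self.models: dict = {}
        self.confidence_sources: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OneVsAllComposite":
        for name in self.class_names:
            backend = self.spec.build_backend()
            backend.fit(X, (y == name).astype(int))
            self.models[name] = backend
            self.confidence_sources[name] = (
                "probability" if hasattr(backend, "predict_proba") else "decision_value"
            )
        return self

    def confidences(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for name in self.class_names:
            backend = self.models[name]
            if hasattr(backend, "predict_proba"):
                proba = backend.predict_proba(X)
                # column of the positive class; a backend that saw only one
                # class in a degenerate relabeling exposes a single column
                idx = int(np.flatnonzero(backend.classes_ == 1)[0]) if 1 in backend.classes_ else 0
                cols.append(proba[:, idx])
            else:
                cols.append(np.asarray(backend.decision_function(X), dtype=float))
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        conf = self.confidences(X)
        # np.argmax returns the first maximum: ties resolve in class order
        return self.class_names[np.argmax(conf, axis=1)]


def _training_arrays(X: LogNormalizedMatrix, y) -> tuple[np.ndarray, np.ndarray]:
    if y is None:
        y = X.labels
    if y is None:
        raise ValueError("training labels required (attach to the matrix or pass y)")
    y = np.asarray(list(y), dtype=object)
    if len(y) != X.n_cells:
        raise ValueError("label vector does not match the matrix cell axis")
    return X.cells_by_features(), y


def train(spec: ClassifierSpec, X: LogNormalizedMatrix, y=None) -> FittedModel:
    """Fit ``spec`` on a feature-restricted training matrix.

    Class order is fixed as the lexicographically sorted unique labels.
    """
    if spec.mode == ONE_VS_ALL:
        return train_one_vs_all(spec, X, y)
    mat, y = _training_arrays(X, y)
    class_names = np.asarray(sorted(set(y)), dtype=object)
    if len(class_names) < 2:
        raise ValueError(f"training data contains a single class: {class_names[0]!r}")
    backend = spec.build_backend()
    backend.fit(mat, y)
    return FittedModel(
        backend=backend, spec=spec, feature_ids=X.gene_ids.copy(), class_names=class_names
    )


def train_one_vs_all(spec: ClassifierSpec, X: LogNormalizedMatrix, y=None, class_names=None) -> FittedModel:
    """Fit one binary backend per class, 1 = class of interest, 0 = rest."""
    if spec.mode != ONE_VS_ALL:
        raise ValueError("spec.mode must be 'one_vs_all'")
    mat, y = _training_arrays(X, y)
    present = set(y)
    if class_names is None:
        class_names = np.asarray(sorted(present), dtype=object)
    else:
        class_names = np.asarray(sorted(class_names), dtype=object)
        absent = [c for c in class_names if c not in present]
        if absent:
            raise ValueError(f"class(es) absent from the training split: {absent}")
    if len(class_names) < 2:
        raise ValueError(f"training data contains a single class: {class_names[0]!r}")
    composite = _OneVsAllComposite(spec, class_names).fit(mat, y)
    return FittedModel(
        backend=composite,
        spec=spec,
        feature_ids=X.gene_ids.copy(),
        class_names=class_names,
        confidence_sources=dict(composite.confidence_sources),
    )


def predict(model: FittedModel, X: LogNormalizedMatrix, y_true=None) -> PredictionSet:
    """Apply a fitted model; the gene axis must match fit-time exactly."""
    if len(X.gene_ids) != len(model.feature_ids) or not np.array_equal(X.gene_ids, model.feature_ids):
        raise ValueError(
            "feature mismatch: the matrix gene axis must equal the model's "
            "feature_ids in the identical order (no silent reordering)"
        )
    if y_true is None:
        y_true = X.labels if X.labels is not None else np.full(X.n_cells, "", dtype=object)
    y_true = np.asarray(list(y_true), dtype=object)
    if X.n_cells == 0:
        empty = np.asarray([], dtype=object)
        return PredictionSet(empty, empty, empty, model.class_names.copy())
    predicted = np.asarray(model.backend.predict(X.cells_by_features()), dtype=object)
    return PredictionSet(
        cell_ids=X.cell_ids.copy(),
        true_labels=y_true,
        predicted_labels=predicted,
        class_names=model.class_names.copy(),
    )


def grid_search(
    family: str,
    grid: HyperparameterGrid,
    train_data: LogNormalizedMatrix,
    validation_data: LogNormalizedMatrix,
    mode: str = MULTICLASS,
    seed: int = 0,
    beta: float = 0.5,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Exhaustive search selecting the highest median validation F-beta.

    Every configuration in the grid's enumeration is fitted on the training
    matrix and scored on the validation matrix by the median per-cluster
    F-beta (clusters with no validation cells are skipped and logged). Ties
    go to the first configuration in enumeration order.
    """
    from .evaluate import confusion, median_f_beta, per_cluster_metrics

    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best: tuple = None
    for i, params in enumerate(grid.enumerate()):
        spec = ClassifierSpec(family=family, mode=mode, hyperparameters=params, seed=seed)
        model = train(spec, train_data)
        preds = predict(model, validation_data)
        metrics = per_cluster_metrics(confusion(preds), beta=beta)
        present = metrics.table[metrics.table["support"] > 0]
        skipped = metrics.table.index[metrics.table["support"] == 0]
        if len(skipped):
            log.info("grid_search config %d: %d cluster(s) absent from validation, skipped", i, len(skipped))
        score = float(np.median(present["f_beta"])) if len(present) else float("nan")
        rows.append({"config_index": i, **params, "median_validation_f_beta": score})
        if best is None or (np.isfinite(score) and score > best[0]):
            best = (score, spec)
    table = pd.DataFrame(rows)
    log.info(
        "grid_search over %d configuration(s): best median validation F-beta %.4f",
        len(rows), best[0],
    )
    return best[1], table
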