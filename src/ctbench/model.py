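"""Model/Results facade over the classifier harness.

``CellTypeClassifier`` binds data (a feature-restricted log-normalised
matrix plus labels) to a :class:`~ctbench.classify.ClassifierSpec`;
``fit()`` returns a :class:`CellTypeClassifierResults` carrying the fitted
backend, evaluation methods and a ``summary()`` table, in the style of
statistical modelling packages. Both delegate to the functional harness in
:mod:`ctbench.classify` and :mod:`ctbench.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, FittedModel, PredictionSet, predict, train
from .containers import LogNormalizedMatrix, SplitAssignment
from .evaluate import (
    ClusterMetrics,
    OverfittingReport,
    confusion,
    median_f_beta,
    overfitting_report,
    per_cluster_metrics,
)


class CellTypeClassifier:
    """A cell-type classification model bound to data and a spec.

    Parameters
    ----------
    data
        Feature-restricted log-normalised expression, genes x cells.
    labels
        Per-cell cluster labels; defaults to ``data.labels``.
    spec
        Family/mode/hyperparameters/seed. Defaults to multinomial logistic
        regression, the benchmark's strongest family.
    """

    def __init__(self, data: LogNormalizedMatrix, labels=None, spec: Optional[ClassifierSpec] = None):
        self.data = data
        self.labels = np.asarray(list(labels), dtype=object) if labels is not None else data.labels
        if self.labels is None:
            raise ValueError("labels are required, either attached to the data or passed explicitly")
        self.spec = spec if spec is not None else ClassifierSpec(family="logistic_regression")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels, spec: Optional[ClassifierSpec] = None):
        """Build from a genes-x-cells DataFrame of log-normalised values."""
        data = LogNormalizedMatrix(
            gene_ids=np.asarray(frame.index.astype(str), dtype=object),
            cell_ids=np.asarray(frame.columns.astype(str), dtype=object),
            values=frame.to_numpy(dtype=float),
        )
        return cls(data, labels=labels, spec=spec)

    def fit(self) -> "CellTypeClassifierResults":
        fitted = train(self.spec, self.data, self.labels)
        return CellTypeClassifierResults(model=self, fitted=fitted)


@dataclass
class CellTypeClassifierResults:
    """Fitted classifier plus evaluation conveniences."""

    model: CellTypeClassifier
    fitted: FittedModel

    @property
    def class_names(self) -> np.ndarray:
        return self.fitted.class_names

    def predict(self, X: LogNormalizedMatrix, y_true=None) -> PredictionSet:
        return predict(self.fitted, X, y_true)

    def evaluate(self, X: LogNormalizedMatrix, y_true=None, beta: float = 0.5) -> ClusterMetrics:
        return per_cluster_metrics(confusion(self.predict(X, y_true)), beta=beta)

    def evaluate_splits(
        self, data: LogNormalizedMatrix, split: SplitAssignment, beta: float = 0.5
    ) -> OverfittingReport:
        return overfitting_report(self.fitted, data, split, beta=beta)

    def summary(self, X: Optional[LogNormalizedMatrix] = None, beta: float = 0.5) -> str:
        spec = self.fitted.spec
        lines = [
            "Cell-type classifier",
            "=" * 52,
            f"family:            {spec.family}",
            f"mode:              {spec.mode}",
            f"hyperparameters:   {spec.hyperparameters or 'defaults'}",
            f"seed:              {spec.seed}",
            f"features (genes):  {len(self.fitted.feature_ids)}",
            f"classes (clusters):{len(self.class_names):>5d}",
            f"training cells:    {self.model.data.n_cells}",
        ]
        if X is not None:
            metrics = self.evaluate(X, beta=beta)
            lines += [
                "-" * 52,
                f"evaluation on {X.n_cells} cells (beta={beta}):",
                f"median per-cluster F-beta: {median_f_beta(metrics):.4f}",
                metrics.table.to_string(float_format=lambda v: f"{v:.4f}"),
            ]
        return "\n".join(lines)
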