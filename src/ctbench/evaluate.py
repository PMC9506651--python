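"""Per-cluster F-beta evaluation and paired model comparison.

Performance is judged per cluster from the confusion matrix: precision P,
recall R and

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R)

with the zero-denominator conventions P = 0 when the cluster is never
predicted, R = 0 when it has no true cells, and F_beta = 0 when
beta^2*P + R = 0. The benchmark default beta = 0.5 weights precision over
recall, discounting recall losses caused by expression dropout. Models are
compared by the distribution of per-cluster F-beta (summarised by its
median) and by the Wilcoxon signed-rank test on paired per-cluster vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .classify import FittedModel, PredictionSet, predict
from .containers import PARTS, LogNormalizedMatrix, SplitAssignment
from .preprocess import split_matrix

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """counts[t, p] = number of cells with true class t predicted as p."""

    class_names: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass
class ClusterMetrics:
    """Per-cluster precision, recall, F-beta and support."""

    table: pd.DataFrame  # index: cluster; columns: precision, recall, f_beta, support
    beta: float

    @property
    def f_beta(self) -> pd.Series:
        return self.table["f_beta"]

    def median_f_beta(self) -> float:
        return median_f_beta(self)


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank result on paired per-cluster values."""

    statistic: float
    p_value: Optional[float]
    n_effective: int
    method: str  # exact | normal_approximation | degenerate

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def confusion(predictions: PredictionSet) -> ConfusionMatrix:
    """Tally a K x K confusion matrix over the prediction set's classes."""
    from sklearn.metrics import confusion_matrix as _sk_confusion

    if len(predictions.cell_ids) == 0:
        raise ValueError("cannot build a confusion matrix from zero predictions")
    classes = set(predictions.class_names)
    outside = (set(predictions.true_labels) | set(predictions.predicted_labels)) - classes
    if outside:
        raise ValueError(f"label(s) outside class_names: {sorted(outside)[:5]}")
    counts = _sk_confusion(
        predictions.true_labels, predictions.predicted_labels, labels=list(predictions.class_names)
    )
    return ConfusionMatrix(class_names=predictions.class_names.copy(), counts=counts)


def f_beta_score(precision: float, recall: float, beta: float) -> float:
    denom = beta**2 * precision + recall
    if denom <= 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def per_cluster_metrics(cm: ConfusionMatrix, beta: float = 0.5) -> ClusterMetrics:
    """Precision/recall/F-beta/support per cluster from a confusion matrix."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    counts = np.asarray(cm.counts, dtype=float)
    tp = np.diag(counts)
    predicted_total = counts.sum(axis=0)
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted_total > 0, tp / predicted_total, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
    fb = np.asarray([f_beta_score(p, r, beta) for p, r in zip(precision, recall)])
    table = pd.DataFrame(
        {"precision": precision, "recall": recall, "f_beta": fb, "support": support.astype(int)},
        index=pd.Index(cm.class_names, name="cluster"),
    )
    return ClusterMetrics(table=table, beta=beta)


def median_f_beta(metrics: ClusterMetrics) -> float:
    """Median of the per-cluster F-beta values (even count: central mean)."""
    if len(metrics.table) == 0:
        raise ValueError("no clusters to take a median over")
    return float(np.median(metrics.table["f_beta"]))


def _exact_sign_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of W+ (in half-rank units) over all 2^n sign assignments.

    Equivalent to full enumeration: a dynamic program that convolves one
    rank at a time, so midrank ties are handled exactly.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y, exact_cutoff: int = 25) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are discarded (classical convention); absolute
    differences are ranked with midranks for ties; the statistic is
    W = min(W+, W-). The p-value is exact (full sign-vector enumeration via
    a convolution that is arithmetically identical to it) for
    n_effective <= ``exact_cutoff``, otherwise a normal approximation with
    continuity correction and midrank tie-variance correction. When every
    difference is zero the result is a degenerate signal with no p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 1")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedComparison(statistic=float("nan"), p_value=None, n_effective=0, method="degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_cutoff:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _exact_sign_distribution(doubled)
        w2 = int(round(2 * w))
        # W+ and W- are exchangeable under H0, so the two-sided p doubles
        # the lower tail of the smaller sum
        p = min(1.0, 2.0 * float(dist[: w2 + 1].sum()) / 2**n)
        return PairedComparison(statistic=w, p_value=p, n_effective=n, method="exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    z = (w - mu + 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return PairedComparison(statistic=w, p_value=p, n_effective=n, method="normal_approximation")


@dataclass
class OverfittingReport:
    """Per-split metrics and the paired split comparisons of one model."""

    metrics: dict  # part -> ClusterMetrics
    comparisons: dict  # (part_a, part_b) -> PairedComparison
    beta: float

    def medians(self) -> dict:
        return {part: median_f_beta(m) for part, m in self.metrics.items()}

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for part, m in self.metrics.items():
            t = m.table.copy()
            t["split"] = part
            t["log2_support"] = np.log2(t["support"].clip(lower=1))
            frames.append(t.reset_index())
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Overfitting report (F-beta, beta=%.2f)" % self.beta]
        for part, med in self.medians().items():
            lines.append(f"  median F-beta [{part:<10s}] = {med:.4f}")
        for (a, b), cmp in self.comparisons.items():
            p = "degenerate (all paired differences zero)" if cmp.degenerate else f"p={cmp.p_value:.3g} ({cmp.method}, n={cmp.n_effective})"
            lines.append(f"  Wilcoxon {a} vs {b}: {p}")
        return "\n".join(lines)


def overfitting_report(
    model: FittedModel,
    data: LogNormalizedMatrix,
    split: SplitAssignment,
    beta: float = 0.5,
) -> OverfittingReport:
    """Predict on train/validation/test and compare their F-beta vectors.

    Comparisons are Wilcoxon signed-rank over the clusters present (support
    > 0) in both members of each pair: (train, validation) and
    (validation, test).
    """
    universe = set(data.cell_ids)
    missing = [c for c in split.cell_ids if c not in universe]
    if missing:
        raise ValueError(
            f"split/model mismatch: {len(missing)} split cell(s) absent from the data "
            f"(e.g. {missing[0]!r})"
        )
    metrics = {}
    for part in PARTS:
        part_matrix = split_matrix(data, split, part)
        preds = predict(model, part_matrix)
        metrics[part] = per_cluster_metrics(confusion(preds), beta=beta)
    comparisons = {}
    for a, b in (("train", "validation"), ("validation", "test")):
        ta, tb = metrics[a].table, metrics[b].table
        shared = ta.index[(ta["support"] > 0) & (tb["support"] > 0)]
        comparisons[(a, b)] = wilcoxon_signed_rank(
            ta.loc[shared, "f_beta"].to_numpy(), tb.loc[shared, "f_beta"].to_numpy()
        )
    return OverfittingReport(metrics=metrics, comparisons=comparisons, beta=beta)


def plot_f_beta_distributions(metrics_by_group: dict, beta: float = 0.5, ax=None):
    """Box plot of per-cluster F-beta distributions, one box per group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(metrics_by_group), 4))
    names = list(metrics_by_group)
    ax.boxplot([metrics_by_group[n].table["f_beta"].to_numpy() for n in names], tick_labels=names)
    ax.set_ylabel(f"per-cluster F-beta (beta={beta})")
    ax.set_ylim(-0.02, 1.02)
    return ax
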