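"""Marker-oriented feature selection on cluster medians.

Two gene scores drive selection, both computed on the MGECT profile
(per-gene, per-cluster medians of log-normalised expression):

* the **binary expression score** (BIN), which rewards "all-or-none"
  cluster-exclusive expression:

      Score(g, X) = sum_i (1 - y_i / y_X)^+  /  (n - 1)

  with y_i the median of gene g in cluster i, y_X the median in the target
  cluster X, n the number of clusters and (.)^+ the positive part. The score
  lives in [0, 1]; 1 means the gene's median is positive only in X. Genes
  with y_X = 0 score 0 (a gene silent in the target cluster cannot mark it).

* the **coefficient of variation** (CV) of the MGECT row,
  sigma(MGECT) / mu(MGECT), which flags genes whose median expression varies
  strongly across cell types regardless of which type they mark.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ClusterMedianProfile, FeatureSet, LogNormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class BinaryScoreTable:
    """Binary expression scores, genes x clusters, each in [0, 1]."""

    gene_ids: np.ndarray
    cluster_names: np.ndarray
    scores: np.ndarray


@dataclass
class CvTable:
    """Per-gene coefficient of variation of the MGECT row.

    ``ddof_mode`` records whether the population (``ddof=0``) or sample
    (``ddof=1``) standard deviation was used.
    """

    gene_ids: np.ndarray
    cv: np.ndarray
    ddof_mode: str = "population"


def binary_scores(profile: ClusterMedianProfile) -> BinaryScoreTable:
    """Binary expression score of every gene for every target cluster."""
    n = profile.n_clusters
    if n < 2:
        raise ValueError(f"binary score needs at least 2 clusters, got {n}")
    y = profile.medians  # (G, n)
    scores = np.zeros_like(y)
    for x in range(n):
        yx = y[:, x]
        pos = yx > 0
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            terms = np.clip(1.0 - y[pos] / yx[pos, None], 0.0, None)
        # the i == X term is (1 - 1)^+ = 0, so summing over all n is safe
        scores[pos, x] = terms.sum(axis=1) / (n - 1)
    return BinaryScoreTable(
        gene_ids=profile.gene_ids.copy(),
        cluster_names=profile.cluster_names.copy(),
        scores=scores,
    )


def select_bin_top_fraction(table: BinaryScoreTable, fraction: float) -> FeatureSet:
    """Top-``fraction`` genes per cluster by binary score, merged.

    Per cluster, genes are ranked by descending score (ties at the cutoff
    broken by ascending gene_id) and the top ceil(fraction * G) taken (at
    least 1); the union over clusters, sorted by gene_id, is returned.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    g = len(table.gene_ids)
    if g == 0:
        raise ValueError("empty score table")
    k = max(1, math.ceil(fraction * g))
    selected: set = set()
    per_cluster: dict = {}
    for x, name in enumerate(table.cluster_names):
        # lexsort: primary key is the last — descending score; ties by gene_id
        order = np.lexsort((table.gene_ids, -table.scores[:, x]))
        chosen = table.gene_ids[order[:k]]
        per_cluster[str(name)] = len(chosen)
        selected.update(chosen)
    gene_ids = np.asarray(sorted(selected), dtype=object)
    return FeatureSet(
        gene_ids=gene_ids,
        provenance={
            "method": "BIN",
            "threshold": fraction,
            "per_cluster_k": k,
            "per_cluster_counts": per_cluster,
            "universe_size": g,
        },
    )


def cv_per_gene(profile: ClusterMedianProfile, ddof_mode: str = "population") -> CvTable:
    """Coefficient of variation sigma/mu of each gene's MGECT row."""
    if ddof_mode not in ("population", "sample"):
        raise ValueError(f"ddof_mode must be 'population' or 'sample', got {ddof_mode!r}")
    ddof = 0 if ddof_mode == "population" else 1
    mu = profile.medians.mean(axis=1)
    if (mu == 0).any():
        bad = profile.gene_ids[np.flatnonzero(mu == 0)[:5]]
        raise ValueError(
            f"gene(s) with zero-mean MGECT reached cv_per_gene (upstream filtering "
            f"violated): {list(bad)}"
        )
    sigma = profile.medians.std(axis=1, ddof=ddof)
    return CvTable(gene_ids=profile.gene_ids.copy(), cv=sigma / mu, ddof_mode=ddof_mode)


def select_cv_threshold(cv: CvTable, threshold: float) -> FeatureSet:
    """Genes with CV >= threshold (inclusive), in ascending gene_id order."""
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    keep = cv.gene_ids[cv.cv >= threshold]
    if keep.size == 0:
        warnings.warn(
            f"CV threshold {threshold} is above every gene's CV; empty feature set",
            stacklevel=2,
        )
    gene_ids = np.asarray(sorted(keep), dtype=object)
    return FeatureSet(
        gene_ids=gene_ids,
        provenance={
            "method": "CV",
            "threshold": threshold,
            "ddof_mode": cv.ddof_mode,
            "universe_size": len(cv.gene_ids),
        },
    )


def subset_matrix(matrix: LogNormalizedMatrix, features: FeatureSet) -> LogNormalizedMatrix:
    """Restrict the gene axis to a feature set, in feature-set order."""
    index = {gid: i for i, gid in enumerate(matrix.gene_ids)}
    missing = [gid for gid in features.gene_ids if gid not in index]
    if missing:
        raise KeyError(f"feature gene(s) absent from the matrix: {missing[:5]}")
    row_idx = np.asarray([index[gid] for gid in features.gene_ids], dtype=int)
    out = matrix.subset_genes(row_idx)
    out.provenance = dict(matrix.provenance)
    out.provenance["feature_selection"] = dict(features.provenance)
    return out
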