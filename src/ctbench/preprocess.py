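"""Normalisation, filtering, cluster medians (MGECT) and the stratified split.

The pipeline order matters and mirrors how atlas-scale snRNA-seq benchmarks
prepare their data: normalise the *full* count matrix to log2(cpm+1) first
(so cpm denominators use the complete gene universe), then drop unassigned
cells, then all-zero genes, then genes whose per-cluster median expression
(MGECT) is constant across clusters — the latter removes both sparsely
expressed genes (all-zero medians) and housekeeping-like genes, neither of
which can separate cell types.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .containers import (
    PARTS,
    UNASSIGNED,
    AnnotatedCountMatrix,
    ClusterMedianProfile,
    LogNormalizedMatrix,
    SplitAssignment,
)

log = logging.getLogger(__name__)

CPM_SCALE = 1e6
PSEUDOCOUNT = 1.0
LOG_BASE = 2


def normalize_cpm_log2(matrix: AnnotatedCountMatrix) -> LogNormalizedMatrix:
    """Counts-per-million followed by log2(cpm + 1), per cell.

    Entry (g, j) becomes log2(counts[g, j] / T_j * 1e6 + 1) where T_j is cell
    j's total raw count over all genes present in ``matrix``. Cells with zero
    total count are rejected by name.
    """
    counts = matrix.counts
    if sp.issparse(counts):
        counts = counts.tocsc().astype(float)
        totals = np.asarray(counts.sum(axis=0)).ravel()
    else:
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total count cannot be cpm-normalized: "
            f"{list(matrix.cell_ids[zero[:5]])}"
        )
    if sp.issparse(counts):
        values = counts.multiply(CPM_SCALE / totals[None, :]).tocsr()
        values.data = np.log2(values.data + PSEUDOCOUNT)
    else:
        values = np.log2(counts / totals[None, :] * CPM_SCALE + PSEUDOCOUNT)
    return LogNormalizedMatrix(
        gene_ids=matrix.gene_ids.copy(),
        cell_ids=matrix.cell_ids.copy(),
        values=values,
        labels=matrix.labels.copy(),
        provenance={
            "normalization": {"scale": CPM_SCALE, "pseudocount": PSEUDOCOUNT, "log_base": LOG_BASE},
            "filters": [],
        },
    )


def _resolve_labels(matrix: LogNormalizedMatrix, labels) -> np.ndarray:
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("no labels attached to the matrix and none supplied")
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("labels length does not match the cell axis")
    return labels


def drop_unlabeled_cells(matrix: LogNormalizedMatrix, labels=None) -> LogNormalizedMatrix:
    """Remove cells whose label is the unassigned sentinel."""
    labels = _resolve_labels(matrix, labels)
    keep = labels != UNASSIGNED
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("all cells are unassigned; nothing left to analyse")
    out = matrix.subset_cells(keep)
    out.labels = labels[keep]
    out.provenance = dict(matrix.provenance)
    out.provenance["filters"] = matrix.provenance.get("filters", []) + [
        {"step": "drop_unlabeled_cells", "removed": n_removed, "remaining_cells": out.n_cells}
    ]
    log.info("drop_unlabeled_cells: removed %d cells, %d labeled cells remain", n_removed, out.n_cells)
    return out


def drop_all_zero_genes(matrix: LogNormalizedMatrix) -> LogNormalizedMatrix:
    """Remove genes with zero expression across every retained cell."""
    vals = matrix.values
    if sp.issparse(vals):
        nonzero_per_gene = np.asarray((vals != 0).sum(axis=1)).ravel()
    else:
        nonzero_per_gene = (np.asarray(vals) != 0).sum(axis=1)
    keep_idx = np.flatnonzero(nonzero_per_gene > 0)
    n_removed = matrix.n_genes - keep_idx.size
    if keep_idx.size == 0:
        log.warning("drop_all_zero_genes: no genes remain")
    out = matrix.subset_genes(keep_idx)
    out.provenance = dict(matrix.provenance)
    out.provenance["filters"] = matrix.provenance.get("filters", []) + [
        {"step": "drop_all_zero_genes", "removed": n_removed, "remaining_genes": out.n_genes}
    ]
    log.info("drop_all_zero_genes: removed %d genes, %d genes remain", n_removed, out.n_genes)
    return out


def compute_mgect(matrix: LogNormalizedMatrix, labels=None) -> ClusterMedianProfile:
    """Median Gene Expression within each Cell Type.

    Per gene and per cluster, the median of the log-normalised values over
    that cluster's cells (even cluster sizes: mean of the two central order
    statistics). Cluster columns are ordered by sorted cluster name.
    """
    labels = _resolve_labels(matrix, labels)
    if (labels == UNASSIGNED).any():
        raise ValueError("compute_mgect requires every cell to carry a cluster label")
    cluster_names = np.asarray(sorted(set(labels)), dtype=object)
    medians = np.empty((matrix.n_genes, len(cluster_names)))
    vals = matrix.values.tocsc() if sp.issparse(matrix.values) else np.asarray(matrix.values)
    for i, name in enumerate(cluster_names):
        cols = np.flatnonzero(labels == name)
        if cols.size == 0:
            raise ValueError(f"cluster {name!r} has no cells")
        block = vals[:, cols]
        if sp.issparse(block):
            block = np.asarray(block.todense())
        medians[:, i] = np.median(block, axis=1)
    return ClusterMedianProfile(gene_ids=matrix.gene_ids.copy(), cluster_names=cluster_names, medians=medians)


def drop_zero_variance_mgect_genes(
    matrix: LogNormalizedMatrix, profile: ClusterMedianProfile
) -> tuple[LogNormalizedMatrix, ClusterMedianProfile]:
    """Remove genes whose MGECT row is exactly constant across clusters.

    After all-zero-gene removal this catches sparsely expressed genes (every
    cluster median 0) and any exactly-constant row — the housekeeping-like
    profile with no between-cluster signal.
    """
    if not np.array_equal(matrix.gene_ids, profile.gene_ids):
        raise ValueError("profile was not computed on the matrix's gene set")
    row_min = profile.medians.min(axis=1)
    row_max = profile.medians.max(axis=1)
    keep_idx = np.flatnonzero(row_max != row_min)  # variance exactly 0 <=> constant row
    n_removed = matrix.n_genes - keep_idx.size
    out = matrix.subset_genes(keep_idx)
    out.provenance = dict(matrix.provenance)
    out.provenance["filters"] = matrix.provenance.get("filters", []) + [
        {"step": "drop_zero_variance_mgect_genes", "removed": n_removed, "remaining_genes": out.n_genes}
    ]
    out_profile = ClusterMedianProfile(
        gene_ids=profile.gene_ids[keep_idx],
        cluster_names=profile.cluster_names.copy(),
        medians=profile.medians[keep_idx, :],
    )
    log.info("drop_zero_variance_mgect_genes: removed %d genes, %d genes remain", n_removed, out.n_genes)
    return out, out_profile


def preprocess_counts(matrix: AnnotatedCountMatrix) -> tuple[LogNormalizedMatrix, ClusterMedianProfile]:
    """Full preprocessing chain: normalise, drop unlabeled cells, drop
    all-zero genes, compute MGECT, drop zero-MGECT-variance genes."""
    normalized = normalize_cpm_log2(matrix)
    normalized = drop_unlabeled_cells(normalized)
    normalized = drop_all_zero_genes(normalized)
    profile = compute_mgect(normalized)
    return drop_zero_variance_mgect_genes(normalized, profile)


def _cluster_rng(seed: int, cluster_name: str) -> np.random.Generator:
    # crc32 gives a platform-stable per-cluster offset, so adding or removing
    # one cluster never perturbs another cluster's permutation.
    return np.random.default_rng([int(seed), zlib.crc32(str(cluster_name).encode())])


def stratified_split(
    labels,
    cell_ids=None,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Train/validation/test split, stratified within each cluster.

    Within a cluster of size m the counts are floor(f_train*m) train,
    floor(f_val*m) validation, and the remainder test — so test is never
    empty for a nonempty cluster. Unassigned cells are excluded. Deterministic
    for a fixed seed; each cluster's permutation is seeded independently.
    """
    labels = np.asarray(list(labels), dtype=object)
    if cell_ids is None:
        cell_ids = np.asarray([f"cell{i}" for i in range(len(labels))], dtype=object)
    cell_ids = np.asarray(list(cell_ids), dtype=object)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(not (0 < f < 1) for f in fractions):
        raise ValueError("fractions must be three values in (0, 1)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    labeled = labels != UNASSIGNED
    if not labeled.any():
        raise ValueError("no labeled cells to split")
    parts = np.empty(int(labeled.sum()), dtype=object)
    kept_ids = cell_ids[labeled]
    kept_labels = labels[labeled]
    for name in sorted(set(kept_labels)):
        idx = np.flatnonzero(kept_labels == name)
        m = idx.size
        if m < 5:
            warnings.warn(
                f"cluster {name!r} has only {m} cell(s); its train or validation part may be empty",
                stacklevel=2,
            )
        n_train = int(np.floor(fractions[0] * m))
        n_val = int(np.floor(fractions[1] * m))
        perm = _cluster_rng(seed, name).permutation(m)
        parts[idx[perm[:n_train]]] = "train"
        parts[idx[perm[n_train : n_train + n_val]]] = "validation"
        parts[idx[perm[n_train + n_val :]]] = "test"
    return SplitAssignment(cell_ids=kept_ids, partition=parts, seed=int(seed), fractions=fractions)


def split_matrix(matrix: LogNormalizedMatrix, split: SplitAssignment, part: str) -> LogNormalizedMatrix:
    """Restrict a matrix's cell axis to one split part (by cell_id)."""
    wanted = set(split.cell_ids[split.mask(part)])
    mask = np.asarray([c in wanted for c in matrix.cell_ids])
    return matrix.subset_cells(mask)
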