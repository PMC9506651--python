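"""Core in-memory containers for the classification benchmark.

All expression matrices are oriented genes (rows) x cells (columns), matching
the convention of count matrices distributed by single-cell atlases; file
readers transpose as needed. Matrices may be dense :class:`numpy.ndarray` or
any :mod:`scipy.sparse` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

#: Canonical label for cells with no cell-type assignment. Readers normalise
#: empty strings, "NA", "NaN" and user-configured sentinels to this value.
UNASSIGNED = "unassigned"

#: Strings treated as "no assignment" when reading label tables.
DEFAULT_UNASSIGNED_TOKENS = frozenset({"", "na", "nan", "none", "unassigned"})


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        seen: set = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


def _as_id_array(ids: Sequence[str]) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


@dataclass
class AnnotatedCountMatrix:
    """Raw nonnegative counts (genes x cells) with per-cell type labels.

    ``labels`` holds one cell-type name per cell; cells without an assignment
    carry :data:`UNASSIGNED`.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: "np.ndarray | sp.spmatrix"
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _as_id_array(self.gene_ids)
        self.cell_ids = _as_id_array(self.cell_ids)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if self.labels is None:
            self.labels = np.full(len(self.cell_ids), UNASSIGNED, dtype=object)
        self.labels = _as_id_array(self.labels)
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels must have exactly one entry per cell")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.tocoo().data.min(initial=0)
        if mn < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense_counts(self) -> np.ndarray:
        return np.asarray(self.counts.todense()) if sp.issparse(self.counts) else np.asarray(self.counts)


@dataclass
class LogNormalizedMatrix:
    """log2(cpm + 1)-transformed expression (genes x cells).

    ``provenance`` records the normalisation parameters (scale, pseudocount,
    log base) plus any filters applied downstream.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: "np.ndarray | sp.spmatrix"
    labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_id_array(self.gene_ids)
        self.cell_ids = _as_id_array(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell identifiers")
        if self.labels is not None:
            self.labels = _as_id_array(self.labels)
            if len(self.labels) != len(self.cell_ids):
                raise ValueError("labels must have exactly one entry per cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense_values(self) -> np.ndarray:
        return np.asarray(self.values.todense()) if sp.issparse(self.values) else np.asarray(self.values)

    def cells_by_features(self) -> np.ndarray:
        """Dense cells x genes view, the orientation classifiers consume."""
        return self.dense_values().T

    def subset_cells(self, mask: np.ndarray) -> "LogNormalizedMatrix":
        vals = self.values.tocsc()[:, mask] if sp.issparse(self.values) else self.values[:, mask]
        return replace(
            self,
            cell_ids=self.cell_ids[mask],
            values=vals,
            labels=None if self.labels is None else self.labels[mask],
        )

    def subset_genes(self, row_idx: np.ndarray) -> "LogNormalizedMatrix":
        vals = self.values.tocsr()[row_idx, :] if sp.issparse(self.values) else self.values[row_idx, :]
        return replace(self, gene_ids=self.gene_ids[row_idx], values=vals)


@dataclass
class ClusterMedianProfile:
    """MGECT: per-gene, per-cluster median of log-normalised expression.

    ``medians[g, i]`` is the median expression of gene ``g`` over the cells of
    cluster ``i`` — the ``y_i`` of the binary expression score, with the
    target cluster's column playing ``y_X`` and ``n = len(cluster_names)``.
    """

    gene_ids: np.ndarray
    cluster_names: np.ndarray
    medians: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _as_id_array(self.gene_ids)
        self.cluster_names = _as_id_array(self.cluster_names)
        self.medians = np.asarray(self.medians, dtype=float)
        if self.medians.shape != (len(self.gene_ids), len(self.cluster_names)):
            raise ValueError("medians shape does not match gene/cluster identifiers")
        if (self.medians < 0).any():
            raise ValueError("MGECT medians must be nonnegative")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_names)


PARTS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Per-cell train/validation/test partition, stratified within cluster."""

    cell_ids: np.ndarray
    partition: np.ndarray
    seed: int
    fractions: tuple

    def __post_init__(self) -> None:
        self.cell_ids = _as_id_array(self.cell_ids)
        self.partition = _as_id_array(self.partition)
        if len(self.partition) != len(self.cell_ids):
            raise ValueError("one partition entry per cell required")
        bad = set(self.partition) - set(PARTS)
        if bad:
            raise ValueError(f"unknown partition value(s): {sorted(bad)}")

    def mask(self, part: str) -> np.ndarray:
        if part not in PARTS:
            raise ValueError(f"unknown split part {part!r}")
        return self.partition == part

    def counts(self) -> dict:
        return {p: int(self.mask(p).sum()) for p in PARTS}


@dataclass
class FeatureSet:
    """Ordered, deduplicated gene list with selection provenance."""

    gene_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_id_array(self.gene_ids)
        _check_unique(self.gene_ids, "feature gene")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)
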