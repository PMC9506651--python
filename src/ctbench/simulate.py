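"""Synthetic labeled count matrices with known ground truth.

The generator emulates the statistical structure the benchmark assumes of a
clustered snRNA-seq count matrix, with four planted gene roles:

* ``marker`` — cluster-exclusive: negative-binomial counts (shifted by one,
  so every home-cluster cell expresses before dropout) in its home cluster
  and exactly zero elsewhere; the "all-or-none" pattern the binary score
  rewards.
* ``graded`` — expressed across a random subset of clusters with expected
  means interpolated between a low and a high level, giving a nonzero CV of
  expected medians; the substrate for CV selection.
* ``sparse`` — expressed in an exact, pre-chosen number of cells per
  cluster, strictly below half the cluster size, so every cluster median is
  exactly zero and the MGECT zero-variance filter must remove the gene.
* ``baseline`` — housekeeping-like uniformity: the same expressing-cell
  fraction (below one half) in every cluster, at a common mean. Because
  library sizes vary cell to cell, a constant positive raw count cannot
  yield an exactly-constant log2(cpm+1) median row, so uniform-rare
  expression (median exactly zero everywhere) is the only construction that
  makes baseline removal by the zero-variance filter deterministic.

Dropout (zero-inflation) independently zeroes each nonzero entry with the
configured probability. Cluster sizes default to log2-uniform over
[16, 512], the regime where small-cluster instability appears.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotatedCountMatrix

log = logging.getLogger(__name__)

ROLES = ("marker", "graded", "sparse", "baseline")


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults define the benchmark's test regime."""

    n_clusters: int = 5
    cluster_sizes: list = None  # explicit sizes; None draws log2-uniform in size_range
    size_range: tuple = (16, 512)
    markers_per_cluster: int = 5
    n_graded_genes: int = 25
    n_sparse_genes: int = 100
    n_baseline_genes: int = 50
    nb_mean_high: float = 30.0
    nb_mean_low: float = 2.0
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.1
    baseline_express_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dropout_rate >= 0.5:
            warnings.warn(
                "dropout_rate >= 0.5: planted marker medians are no longer guaranteed "
                "positive; filter-exactness oracles will refuse this truth",
                stacklevel=2,
            )
        if not (0 < self.baseline_express_fraction < 0.5):
            raise ValueError("baseline_express_fraction must be in (0, 0.5)")
        for name in ("nb_mean_high", "nb_mean_low", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_sizes is not None:
            self.cluster_sizes = [int(s) for s in self.cluster_sizes]
            if len(self.cluster_sizes) != self.n_clusters:
                raise ValueError("cluster_sizes length must equal n_clusters")
            if any(s < 2 for s in self.cluster_sizes):
                raise ValueError("cluster sizes must be at least 2")


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth for a generated matrix."""

    roles: pd.Series  # gene_id -> role
    marker_cluster: dict  # marker gene_id -> home cluster name
    expected_filtered: pd.Series  # gene_id -> bool (must the MGECT filter remove it?)
    expected_means: pd.DataFrame  # genes x clusters expected count-scale means
    dropout_rate: float

    def genes_with_role(self, role: str) -> list:
        return list(self.roles.index[self.roles == role])


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # NB parametrised by mean mu and dispersion r: p = r / (r + mu)
    r = dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def generate(spec: SyntheticSpec) -> tuple[AnnotatedCountMatrix, SyntheticTruth]:
    """Draw a labeled count matrix plus its planted truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    if spec.cluster_sizes is not None:
        sizes = list(spec.cluster_sizes)
    else:
        lo, hi = np.log2(spec.size_range[0]), np.log2(spec.size_range[1])
        sizes = [int(round(2 ** rng.uniform(lo, hi))) for _ in range(k)]
    cluster_names = [f"cluster{i:02d}" for i in range(k)]
    boundaries = np.concatenate([[0], np.cumsum(sizes)])
    n_cells = int(boundaries[-1])
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    labels = np.empty(n_cells, dtype=object)
    cluster_cells = {}
    for i, name in enumerate(cluster_names):
        sl = slice(int(boundaries[i]), int(boundaries[i + 1]))
        labels[sl] = name
        cluster_cells[name] = np.arange(sl.start, sl.stop)

    gene_ids, roles, marker_cluster = [], [], {}
    n_markers = k * spec.markers_per_cluster
    for i in range(n_markers):
        gene_ids.append(f"MK{i:04d}")
        roles.append("marker")
        marker_cluster[f"MK{i:04d}"] = cluster_names[i % k]
    gene_ids += [f"GR{i:04d}" for i in range(spec.n_graded_genes)]
    roles += ["graded"] * spec.n_graded_genes
    gene_ids += [f"SP{i:04d}" for i in range(spec.n_sparse_genes)]
    roles += ["sparse"] * spec.n_sparse_genes
    gene_ids += [f"BL{i:04d}" for i in range(spec.n_baseline_genes)]
    roles += ["baseline"] * spec.n_baseline_genes
    g = len(gene_ids)

    counts = np.zeros((g, n_cells), dtype=np.int64)
    expected = np.zeros((g, k))
    row_of = {gid: i for i, gid in enumerate(gene_ids)}

    for gid in [x for x in gene_ids if x.startswith("MK")]:
        home = marker_cluster[gid]
        cells = cluster_cells[home]
        # +1 guarantees expression in every home-cluster cell before dropout
        counts[row_of[gid], cells] = 1 + _nb_draw(rng, spec.nb_mean_high - 1, spec.nb_dispersion, cells.size)
        expected[row_of[gid], cluster_names.index(home)] = spec.nb_mean_high

    for gid in [x for x in gene_ids if x.startswith("GR")]:
        subset_size = int(rng.integers(2, k + 1))
        subset = rng.choice(k, size=subset_size, replace=False)
        means = np.full(k, spec.nb_mean_low)
        means[subset] = np.linspace(spec.nb_mean_low, spec.nb_mean_high, subset_size)
        for ci, name in enumerate(cluster_names):
            cells = cluster_cells[name]
            counts[row_of[gid], cells] = _nb_draw(rng, means[ci], spec.nb_dispersion, cells.size)
        expected[row_of[gid]] = means

    for gid in [x for x in gene_ids if x.startswith("SP")]:
        for ci, name in enumerate(cluster_names):
            m = len(cluster_cells[name])
            max_expr = (m - 1) // 2  # strictly below half
            n_expr = int(rng.integers(1, max_expr + 1)) if max_expr >= 1 else 0
            if n_expr:
                chosen = rng.choice(cluster_cells[name], size=n_expr, replace=False)
                counts[row_of[gid], chosen] = 1 + _nb_draw(rng, spec.nb_mean_low, spec.nb_dispersion, n_expr)
            expected[row_of[gid], ci] = n_expr * (1 + spec.nb_mean_low) / m

    for gid in [x for x in gene_ids if x.startswith("BL")]:
        for ci, name in enumerate(cluster_names):
            m = len(cluster_cells[name])
            n_expr = min(max(1, int(math.floor(spec.baseline_express_fraction * m))), (m - 1) // 2)
            if n_expr:
                chosen = rng.choice(cluster_cells[name], size=n_expr, replace=False)
                counts[row_of[gid], chosen] = 1 + _nb_draw(rng, spec.nb_mean_low, spec.nb_dispersion, n_expr)
            expected[row_of[gid], ci] = n_expr * (1 + spec.nb_mean_low) / m

    if spec.dropout_rate > 0:
        nz = counts > 0
        drop = rng.random(counts.shape) < spec.dropout_rate
        counts[nz & drop] = 0

    roles_s = pd.Series(roles, index=pd.Index(gene_ids, name="gene_id"), name="role")
    truth = SyntheticTruth(
        roles=roles_s,
        marker_cluster=marker_cluster,
        expected_filtered=roles_s.isin(["sparse", "baseline"]).rename("expected_filtered"),
        expected_means=pd.DataFrame(expected, index=gene_ids, columns=cluster_names),
        dropout_rate=spec.dropout_rate,
    )
    matrix = AnnotatedCountMatrix(
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        counts=counts,
        labels=labels,
    )
    log.info(
        "generated synthetic matrix: %d genes x %d cells, %d clusters (sizes %s)",
        g, n_cells, k, sizes,
    )
    return matrix, truth


def truth_filter_oracle(truth: SyntheticTruth) -> set:
    """The gene set preprocessing must retain: markers and graded genes.

    Refuses when dropout >= 0.5, where marker medians are no longer
    guaranteed positive and the survivor set stops being well-defined.
    """
    if truth.dropout_rate >= 0.5:
        raise ValueError(
            f"truth oracle undefined at dropout_rate={truth.dropout_rate}: marker "
            "medians are not guaranteed positive at or above 0.5"
        )
    return set(truth.roles.index[~truth.expected_filtered])


def write_synthetic_dataset(matrix: AnnotatedCountMatrix, truth: SyntheticTruth, out_dir) -> dict:
    """Persist a generated dataset in both input formats plus truth JSON."""
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "counts.mtx",
        "dense": out_dir / "counts.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.json",
    }
    _io.write_count_matrix(matrix, paths["mtx"], format="mtx_triplet")
    _io.write_count_matrix(matrix, paths["dense"], format="dense_delimited")
    _io.write_labels(matrix, paths["labels"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "roles": truth.roles.to_dict(),
                "marker_cluster": truth.marker_cluster,
                "expected_filtered": {k: bool(v) for k, v in truth.expected_filtered.items()},
                "dropout_rate": truth.dropout_rate,
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}
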