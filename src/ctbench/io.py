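"""Readers and writers for count matrices, labels, splits and feature sets.

Supported on-disk layouts:

* ``mtx_triplet`` — a Matrix Market coordinate file (genes x cells) with
  sidecar name files ``<stem>.genes.txt`` and ``<stem>.cells.txt`` (one
  identifier per line), the layout used by most droplet pipelines.
* ``dense_delimited`` — TSV/CSV with gene rows, a header row of cell
  identifiers and a leading gene-identifier column.

Labels are a two-column delimited table ``cell_id<sep>cell_type`` with a
header row; empty or NA-like cell types mean "no assignment".
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    DEFAULT_UNASSIGNED_TOKENS,
    UNASSIGNED,
    AnnotatedCountMatrix,
    FeatureSet,
    LogNormalizedMatrix,
    SplitAssignment,
)

log = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_ids(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"sidecar name file not found: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_count_matrix(path, format: str = None) -> AnnotatedCountMatrix:
    """Read a genes x cells count matrix; labels start out unassigned.

    ``format`` is ``"mtx_triplet"`` or ``"dense_delimited"``; when omitted it
    is inferred from the file suffix (``.mtx`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    if format is None:
        format = "mtx_triplet" if path.suffix.lower() == ".mtx" else "dense_delimited"
    if format == "mtx_triplet":
        genes_path, cells_path = sidecar_paths(path)
        counts = sp.csr_matrix(scipy.io.mmread(path))
        gene_ids, cell_ids = _read_ids(genes_path), _read_ids(cells_path)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
    elif format == "dense_delimited":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        if df.isna().any().any():
            raise ValueError(f"non-numeric or missing entries in {path}")
        gene_ids = np.asarray(df.index.astype(str), dtype=object)
        cell_ids = np.asarray(df.columns.astype(str), dtype=object)
        counts = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    if (counts < 0).sum() if not sp.issparse(counts) else (counts.data < 0).sum():
        raise ValueError("negative count entries are not allowed")
    return AnnotatedCountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        labels=np.full(len(cell_ids), UNASSIGNED, dtype=object),
    )


def read_labels(
    path,
    matrix: AnnotatedCountMatrix,
    unassigned_tokens=DEFAULT_UNASSIGNED_TOKENS,
) -> AnnotatedCountMatrix:
    """Attach cell-type labels from a 2-column table by cell_id join.

    Cells absent from the file stay unassigned; rows naming unknown cells are
    ignored with a warning.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str, keep_default_na=False)
    if table.shape[1] != 2:
        raise ValueError(f"label file must have exactly 2 columns, got {table.shape[1]}")
    labels = np.full(matrix.n_cells, UNASSIGNED, dtype=object)
    index = {c: i for i, c in enumerate(matrix.cell_ids)}
    unknown = []
    for cell_id, cell_type in table.itertuples(index=False):
        if cell_id not in index:
            unknown.append(cell_id)
            continue
        if cell_type.strip().lower() in unassigned_tokens:
            labels[index[cell_id]] = UNASSIGNED
        else:
            labels[index[cell_id]] = cell_type
    if unknown:
        warnings.warn(
            f"{len(unknown)} label row(s) name cells absent from the matrix "
            f"(e.g. {unknown[0]!r}); ignored",
            stacklevel=2,
        )
    matrix.labels = labels
    return matrix


# ---------------------------------------------------------------- writers


def write_count_matrix(matrix: AnnotatedCountMatrix, path, format: str = "mtx_triplet") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx_triplet":
        genes_path, cells_path = sidecar_paths(path)
        scipy.io.mmwrite(str(path), sp.coo_matrix(matrix.counts))
        genes_path.write_text("\n".join(matrix.gene_ids) + "\n")
        cells_path.write_text("\n".join(matrix.cell_ids) + "\n")
    elif format == "dense_delimited":
        pd.DataFrame(
            matrix.dense_counts(), index=matrix.gene_ids, columns=matrix.cell_ids
        ).to_csv(path, sep=_sep_for(path))
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


def write_labels(matrix: AnnotatedCountMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": matrix.cell_ids, "cell_type": matrix.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_normalized_matrix(matrix: LogNormalizedMatrix, path) -> None:
    """Dense delimited dump of a log-normalised matrix plus JSON provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        matrix.dense_values(), index=matrix.gene_ids, columns=matrix.cell_ids
    ).to_csv(path, sep=_sep_for(path))
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump(matrix.provenance, fh, indent=2, default=str)


def read_normalized_matrix(path, labels_path=None) -> LogNormalizedMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    prov_path = path.with_suffix(path.suffix + ".provenance.json")
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    labels = None
    if labels_path is not None:
        table = pd.read_csv(Path(labels_path), sep=_sep_for(Path(labels_path)), dtype=str, keep_default_na=False)
        mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
        labels = np.asarray(
            [mapping.get(str(c), UNASSIGNED) or UNASSIGNED for c in df.columns], dtype=object
        )
    return LogNormalizedMatrix(
        gene_ids=np.asarray(df.index.astype(str), dtype=object),
        cell_ids=np.asarray(df.columns.astype(str), dtype=object),
        values=df.to_numpy(dtype=float),
        labels=labels,
        provenance=provenance,
    )


def write_split(split: SplitAssignment, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": split.cell_ids, "partition": split.partition}).to_csv(
        path, sep=_sep_for(path), index=False
    )
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump({"seed": split.seed, "fractions": list(split.fractions)}, fh, indent=2)


def read_split(path) -> SplitAssignment:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    prov_path = path.with_suffix(path.suffix + ".provenance.json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {"seed": -1, "fractions": [0.6, 0.2, 0.2]}
    return SplitAssignment(
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        partition=df["partition"].to_numpy(dtype=object),
        seed=int(prov["seed"]),
        fractions=tuple(prov["fractions"]),
    )


def write_feature_set(features: FeatureSet, path) -> None:
    """One gene id per line plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(features.gene_ids) + ("\n" if len(features) else ""))
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump(features.provenance, fh, indent=2, default=str)


def read_feature_set(path) -> FeatureSet:
    path = Path(path)
    gene_ids = _read_ids(path) if path.stat().st_size else np.asarray([], dtype=object)
    prov_path = path.with_suffix(path.suffix + ".provenance.json")
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return FeatureSet(gene_ids=gene_ids, provenance=provenance)
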