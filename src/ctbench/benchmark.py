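"""End-to-end benchmark orchestration from a declarative config.

A single YAML config describes the input (a count matrix + labels on disk,
or a synthetic-data spec), the feature-selection method and thresholds, the
split, the classifier specs/grids and beta. ``run_benchmark`` executes
simulate/ingest -> preprocess -> select features -> split -> (grid-search +)
train -> evaluate, persists every intermediate artifact beside a
machine-readable summary, and is idempotent for fixed seeds.
"""

from __future__ import annotations

import json
import logging
import pickle
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as _io
from .classify import ClassifierSpec, HyperparameterGrid, grid_search, predict, train
from .containers import LogNormalizedMatrix, SplitAssignment
from .evaluate import overfitting_report
from .features import (
    binary_scores,
    cv_per_gene,
    select_bin_top_fraction,
    select_cv_threshold,
    subset_matrix,
)
from .preprocess import preprocess_counts, split_matrix, stratified_split
from .simulate import SyntheticSpec, generate, write_synthetic_dataset

log = logging.getLogger(__name__)


class InputSection(BaseModel):
    counts: str
    format: Optional[Literal["mtx_triplet", "dense_delimited"]] = None
    labels: str


class SyntheticSection(BaseModel):
    n_clusters: int = 5
    cluster_sizes: Optional[List[int]] = None
    size_range: List[int] = [16, 512]
    markers_per_cluster: int = 5
    n_graded_genes: int = 25
    n_sparse_genes: int = 100
    n_baseline_genes: int = 50
    nb_mean_high: float = 30.0
    nb_mean_low: float = 2.0
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.1
    seed: int = 0

    def to_spec(self) -> SyntheticSpec:
        d = self.model_dump()
        d["size_range"] = tuple(d.pop("size_range"))
        return SyntheticSpec(**d)


class FeatureSelectionSection(BaseModel):
    method: Literal["CV", "BIN"] = "CV"
    thresholds: List[float] = [1.5]
    ddof_mode: Literal["population", "sample"] = "population"


class SplitSection(BaseModel):
    fractions: List[float] = [0.6, 0.2, 0.2]
    seed: int = 0

    @field_validator("fractions")
    @classmethod
    def _three_fractions(cls, v):
        if len(v) != 3:
            raise ValueError("fractions must have exactly 3 entries")
        return v


class ClassifierSection(BaseModel):
    family: str
    mode: Literal["multiclass", "one_vs_all"] = "multiclass"
    hyperparameters: dict = Field(default_factory=dict)
    grid: Optional[dict] = None
    seed: int = 0


class BenchmarkConfig(BaseModel):
    """The validated schema of a benchmark run."""

    input: Optional[InputSection] = None
    synthetic: Optional[SyntheticSection] = None
    feature_selection: FeatureSelectionSection = Field(default_factory=FeatureSelectionSection)
    split: SplitSection = Field(default_factory=SplitSection)
    classifiers: List[ClassifierSection] = Field(
        default_factory=lambda: [ClassifierSection(family="logistic_regression")]
    )
    beta: float = 0.5
    output_dir: str = "ctbench_out"
    persist_matrix: bool = True
    persist_models: bool = True

    @model_validator(mode="after")
    def _one_input(self):
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'input' and 'synthetic' must be given")
        return self

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass
class BenchmarkReport:
    """Per-combination metrics plus provenance; mirrors the files on disk."""

    records: list  # one dict per (feature set x classifier)
    provenance: dict
    output_dir: Path

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        raise RuntimeError(f"benchmark stage '{name}' failed: {exc}") from exc


def _threshold_tag(value: float) -> str:
    return str(value).replace(".", "p")


def _load_or_simulate(config: BenchmarkConfig, out: Path):
    if config.synthetic is not None:
        matrix, truth = generate(config.synthetic.to_spec())
        write_synthetic_dataset(matrix, truth, out / "synthetic")
        return matrix
    matrix = _io.read_count_matrix(config.input.counts, format=config.input.format)
    return _io.read_labels(config.input.labels, matrix)


def _select(profile, method: str, threshold: float, ddof_mode: str):
    if method == "BIN":
        return select_bin_top_fraction(binary_scores(profile), threshold)
    return select_cv_threshold(cv_per_gene(profile, ddof_mode=ddof_mode), threshold)


def _comparison_json(comparisons: dict) -> dict:
    out = {}
    for (a, b), cmp in comparisons.items():
        out[f"{a}_vs_{b}"] = {
            "statistic": None if np.isnan(cmp.statistic) else cmp.statistic,
            "p_value": cmp.p_value,
            "n_effective": cmp.n_effective,
            "method": cmp.method,
        }
    return out


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Execute the full pipeline described by ``config`` and persist it."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)

    with _stage("ingest"):
        raw = _load_or_simulate(config, out)
    with _stage("preprocess"):
        filtered, profile = preprocess_counts(raw)
        if config.persist_matrix:
            _io.write_normalized_matrix(filtered, out / "filtered_matrix.tsv")
    with _stage("split"):
        split = stratified_split(
            filtered.labels,
            cell_ids=filtered.cell_ids,
            fractions=tuple(config.split.fractions),
            seed=config.split.seed,
        )
        _io.write_split(split, out / "split.tsv")

    fs = config.feature_selection
    records = []
    for threshold in fs.thresholds:
        tag = f"{fs.method}_{_threshold_tag(threshold)}"
        with _stage("feature_selection"):
            features = _select(profile, fs.method, threshold, fs.ddof_mode)
            if len(features) == 0:
                raise ValueError(
                    f"feature selection {fs.method} at threshold {threshold} produced an "
                    "empty feature set"
                )
            _io.write_feature_set(features, out / f"features_{tag}.txt")
            restricted = subset_matrix(filtered, features)
        train_matrix = split_matrix(restricted, split, "train")
        val_matrix = split_matrix(restricted, split, "validation")
        for clf in config.classifiers:
            combo = f"{tag}_{clf.family}_{clf.mode}"
            with _stage("train"):
                if clf.grid:
                    best_spec, table = grid_search(
                        clf.family,
                        HyperparameterGrid(dict(clf.grid)),
                        train_matrix,
                        val_matrix,
                        mode=clf.mode,
                        seed=clf.seed,
                        beta=config.beta,
                    )
                    table.to_csv(out / f"grid_{combo}.tsv", sep="\t", index=False)
                else:
                    best_spec = ClassifierSpec(
                        family=clf.family, mode=clf.mode,
                        hyperparameters=dict(clf.hyperparameters), seed=clf.seed,
                    )
                model = train(best_spec, train_matrix)
                if config.persist_models:
                    _persist_model(model, out / "models" / combo)
            with _stage("evaluate"):
                report = overfitting_report(model, restricted, split, beta=config.beta)
                report.to_frame().to_csv(out / f"metrics_{combo}.tsv", sep="\t", index=False)
            records.append(
                {
                    "feature_method": fs.method,
                    "threshold": threshold,
                    "n_features": len(features),
                    "family": clf.family,
                    "mode": clf.mode,
                    "hyperparameters": dict(best_spec.hyperparameters),
                    **{f"median_f_beta_{part}": med for part, med in report.medians().items()},
                    "comparisons": _comparison_json(report.comparisons),
                }
            )
            log.info("benchmark combo %s: medians %s", combo, report.medians())

    provenance = {
        "filters": filtered.provenance.get("filters", []),
        "split_seed": config.split.seed,
        "beta": config.beta,
        "n_clusters": len(set(filtered.labels)),
        "n_genes_retained": int(filtered.n_genes),
        "n_cells_retained": int(filtered.n_cells),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump({"records": records, "provenance": provenance}, fh, indent=2, sort_keys=True)
    return BenchmarkReport(records=records, provenance=provenance, output_dir=out)


def _persist_model(model, base: Path) -> None:
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".pkl"), "wb") as fh:
        pickle.dump(model.backend, fh)
    sidecar = {
        "spec": {
            "family": model.spec.family,
            "mode": model.spec.mode,
            "hyperparameters": model.spec.hyperparameters,
            "seed": model.spec.seed,
        },
        "feature_ids": list(model.feature_ids),
        "class_names": list(model.class_names),
        "confidence_sources": model.confidence_sources,
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_tuned_specs(path) -> list:
    """Read classifier specs (as written by a previous run or by hand)."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    return [
        ClassifierSpec(
            family=entry["family"],
            mode=entry.get("mode", "multiclass"),
            hyperparameters=entry.get("hyperparameters", {}),
            seed=entry.get("seed", 0),
        )
        for entry in raw
    ]


def transfer_evaluate(config: BenchmarkConfig, tuned_specs: list) -> BenchmarkReport:
    """Apply hyperparameters tuned on another dataset: no grid search here.

    Feature selection is re-run on this config's data; each tuned spec is
    trained on the new train split and evaluated as usual.
    """
    transferred = config.model_copy(deep=True)
    transferred.classifiers = [
        ClassifierSection(
            family=s.family, mode=s.mode, hyperparameters=dict(s.hyperparameters),
            grid=None, seed=s.seed,
        )
        for s in tuned_specs
    ]
    return run_benchmark(transferred)
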