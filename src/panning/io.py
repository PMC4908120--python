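"""Data ingestion, full-pipeline orchestration and results serialization.

Covariate matrices are read from CSV/TSV with samples in rows (transpose on
request); responses from a single-column file or a named column.  A full
run produces a versioned JSON document embedding a manifest (configuration
echo, seeds, input digests, software version, wall time) plus the
per-dimension records, the selected dimension, the filtered model set and
the network.  Covariate indices are 1-based in every output and 0-based
internally; covariate identifiers are the input column names when present.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .divergence import DivergenceSpec
from .network import build_network, export_network
from .risk import CandidateModel, ConfigurationError, Dataset, EstimatorSpec
from .search import DimensionRecord, SearchConfig, run_panning
from .selection import (
    PanningResult,
    TestSpec,
    dimension_test_pvalues,
    filter_model_set,
    select_dimension,
)

__all__ = [
    "read_matrix",
    "read_response",
    "load_dataset",
    "run_analysis",
    "result_to_dict",
    "write_results",
    "load_results",
]

SCHEMA_VERSION = 1


def _read_table(path, sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_matrix(path, transpose: bool = False, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a numeric covariate matrix; samples in rows unless ``transpose``.

    A leading non-numeric column is treated as sample identifiers.
    """
    df = _read_table(path, sep)
    if df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
    if transpose:
        df = df.T
    if not all(pd.api.types.is_numeric_dtype(df[c]) for c in df.columns):
        raise ConfigurationError(f"non-numeric covariate columns in {path}")
    return df


def read_response(path, column: Optional[str] = None, sep: Optional[str] = None) -> pd.Series:
    """Read the response vector from a single-column file or a named column."""
    df = _read_table(path, sep)
    if column is not None:
        if column not in df.columns:
            raise ConfigurationError(f"response column {column!r} not in {path}")
        return df[column]
    numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if len(numeric) < 1:
        raise ConfigurationError(f"no numeric response column found in {path}")
    return df[numeric[-1]]


def load_dataset(
    x_path,
    y_path,
    transpose: bool = False,
    y_column: Optional[str] = None,
) -> Dataset:
    X = read_matrix(x_path, transpose=transpose)
    y = read_response(y_path, column=y_column)
    if len(y) != X.shape[0]:
        raise ConfigurationError(
            f"shape mismatch: X has {X.shape[0]} samples but y has {len(y)}"
        )
    return Dataset(
        X=X.to_numpy(dtype=float),
        y=y.to_numpy(dtype=float),
        feature_ids=[str(c) for c in X.columns],
        sample_ids=[str(i) for i in X.index],
    )


def run_analysis(
    dataset: Dataset,
    config: SearchConfig,
    espec: Optional[EstimatorSpec] = None,
    div: Optional[DivergenceSpec] = None,
    tspec: Optional[TestSpec] = None,
) -> PanningResult:
    """Search + dimension selection + filtering + network, end to end."""
    espec = EstimatorSpec() if espec is None else espec
    div = DivergenceSpec() if div is None else div
    if tspec is None:
        default_test = "proportion_binomial" if div.kind == "classification" else "mann_whitney"
        tspec = TestSpec(test=default_test)
    records = run_panning(dataset, config, espec, div)
    pvalues = dimension_test_pvalues(records, tspec)
    d_star = select_dimension(records, tspec)
    record = records[d_star - 1]
    filtered = filter_model_set(record, tspec)
    net = build_network(filtered, feature_ids=dataset.feature_ids)
    return PanningResult(
        records=records,
        d_star=d_star,
        final_models=list(record.promising_models),
        filtered_models=filtered,
        network=net,
        config_echo=config,
        dimension_pvalues=pvalues,
    )


def _model_to_dict(m: CandidateModel) -> Dict:
    return {"indices": [i + 1 for i in m.indices], "risk": m.risk}


def _record_to_dict(r: DimensionRecord) -> Dict:
    return {
        "d": r.d,
        "n_evaluated": len(r.evaluated),
        "n_sampled": r.sampled_count,
        "exhaustive": r.exhaustive,
        "q_alpha": r.q_alpha,
        "promising_models": [_model_to_dict(m) for m in r.promising_models],
        "promising_indices": sorted(i + 1 for i in r.promising_indices),
    }


def result_to_dict(
    result: PanningResult,
    dataset: Dataset,
    manifest_extra: Optional[Dict] = None,
) -> Dict:
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "config": asdict(result.config_echo),
        "n": dataset.n,
        "p": dataset.p,
        "wall_time": time.time(),
    }
    manifest.update(manifest_extra or {})
    return {
        "manifest": manifest,
        "records": [_record_to_dict(r) for r in result.records],
        "dimension_pvalues": result.dimension_pvalues,
        "d_star": result.d_star,
        "n_final_models": len(result.final_models),
        "filtered_models": [_model_to_dict(m) for m in result.filtered_models],
        "feature_ids": list(dataset.feature_ids),
        "network": json.loads(export_network(result.network, "json")),
    }


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(payload: Dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_results(path) -> Dict:
    return json.loads(Path(path).read_text())


def filtered_models_from_results(payload: Dict) -> List[CandidateModel]:
    """Rebuild the filtered model set (0-based indices) from a results file."""
    return [
        CandidateModel(indices=tuple(i - 1 for i in m["indices"]), risk=m["risk"])
        for m in payload["filtered_models"]
    ]
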