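"""Readers and writers: count matrices (TSV/CSV/MatrixMarket), group
metadata, scenario configs (YAML/JSON) and result tables (TSV).

Count files follow the dominant DE convention: genes in rows, samples in
columns, first column the gene id. Group membership lives in a separate
two-column table (sample_id, group) so that the blinding of the filters to
the group labels stays auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .containers import (CountMatrix, FilterSpec, ScenarioConfig,
                         ConfigError, FormatError)

__all__ = ["read_counts", "write_counts", "read_groups", "write_groups",
           "read_config", "write_results"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise FormatError(f"cannot infer count format from {path.name!r}")


def read_groups(path) -> pd.Series:
    """Two-column table sample_id -> group label (1 or 2)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError("group metadata needs columns (sample_id, group)")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return ser


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}) \
        .to_csv(path, sep="\t", index=False)


def read_counts(path, groups_path=None, fmt: str | None = None,
                groups=None) -> CountMatrix:
    """Read a count matrix and its sample-to-group assignment.

    TSV/CSV: header row of sample ids, first column gene ids. MTX: sidecar
    files <stem>.rownames.txt / <stem>.colnames.txt carry gene and sample ids.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric counts in {path.name}: {exc}") from exc
        gene_ids = df.index.astype(str).to_numpy(dtype=object)
        sample_ids = df.columns.astype(str).to_numpy(dtype=object)
    elif fmt == "mtx":
        mat = mmread(path)
        values = np.asarray(mat.toarray() if hasattr(mat, "toarray") else mat)
        gene_ids = np.loadtxt(path.with_suffix(".rownames.txt"), dtype=str,
                              ndmin=1).astype(object)
        sample_ids = np.loadtxt(path.with_suffix(".colnames.txt"), dtype=str,
                                ndmin=1).astype(object)
    else:
        raise FormatError(f"unsupported count format {fmt!r}")

    if groups is None:
        if groups_path is None:
            raise FormatError("group metadata is required")
        groups = read_groups(groups_path)
    if isinstance(groups, pd.Series):
        missing = [s for s in sample_ids if s not in groups.index]
        if missing:
            raise FormatError(f"samples missing from group metadata: {missing}")
        groups = groups.loc[list(sample_ids)].to_numpy()
    try:
        return CountMatrix(values, gene_ids, sample_ids, groups)
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_counts(cm: CountMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(cm.counts, index=pd.Index(cm.gene_ids, name="gene_id"),
                     columns=cm.sample_ids).to_csv(path, sep=sep)
    elif fmt == "mtx":
        mmwrite(str(path), csr_matrix(cm.counts))
        np.savetxt(path.with_suffix(".rownames.txt"), cm.gene_ids, fmt="%s")
        np.savetxt(path.with_suffix(".colnames.txt"), cm.sample_ids, fmt="%s")
    else:
        raise FormatError(f"unsupported count format {fmt!r}")


def _parse_filter(entry) -> FilterSpec:
    if isinstance(entry, str):
        return FilterSpec(entry)
    if isinstance(entry, dict):
        return FilterSpec(entry["family"], entry.get("threshold"))
    raise ConfigError(f"cannot parse filter spec {entry!r}")


def read_config(path) -> ScenarioConfig:
    """Read a YAML or JSON scenario config, validated on construction."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    kwargs = dict(data)
    if "filter_battery" in kwargs and kwargs["filter_battery"] is not None:
        kwargs["filter_battery"] = tuple(_parse_filter(e)
                                         for e in kwargs["filter_battery"])
    if "reference" in kwargs:
        kwargs["reference"] = _parse_filter(kwargs["reference"])
    try:
        return ScenarioConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def write_results(metrics, path) -> None:
    """Plain TSV, one row per (scenario, filter)."""
    table = metrics.table if hasattr(metrics, "table") else metrics
    table.to_csv(path, sep="\t", index=False)
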