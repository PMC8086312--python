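"""Readers and writers for expression matrices, sample tables, ortholog maps
and serialized model bundles.

Supported matrix formats: TSV/CSV with a header row and the gene id in the
first column, and GCT dialect 1.2 (``#1.2`` version line, then a
``<genes>\\t<samples>`` dimension line; the Description column is dropped).
Duplicate gene rows are collapsed — summed for counts (preserves library size
for downsampling), averaged for intensities — with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, OrthologMap, SampleAnnotation

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "read_ortholog_map",
    "save_model",
    "load_model",
]

BUNDLE_FORMAT_VERSION = 1


def _collapse_duplicate_genes(df: pd.DataFrame, value_kind: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    n_dup = int(df.index.duplicated().sum())
    how = "sum" if value_kind == "counts" else "mean"
    warnings.warn(
        f"{n_dup} duplicate gene rows collapsed by {how}", stacklevel=3
    )
    grouped = df.groupby(level=0, sort=False)
    return grouped.sum() if how == "sum" else grouped.mean()


def read_expression_matrix(
    path, format: Optional[str] = None, value_kind: str = "counts"
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV, CSV or GCT 1.2.

    ``format`` is inferred from the file suffix when omitted.  The first
    column of TSV/CSV holds gene ids; GCT follows the 1.2 dialect.
    """
    path = Path(path)
    if format is None:
        format = {".gct": "gct", ".csv": "csv"}.get(path.suffix.lower(), "tsv")
    if format not in ("tsv", "csv", "gct"):
        raise ValueError(f"unsupported format {format!r}")

    if format == "gct":
        df = _read_gct(path)
    else:
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            dups = sorted({c for c in header if header.count(c) > 1})
            raise ValueError(f"duplicate sample ids in {path.name}: {dups[:10]}")
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df = _collapse_duplicate_genes(df, value_kind)
    return ExpressionMatrix(df, value_kind)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(
                f"{path.name} line 1: expected GCT version line '#1.2', got {version!r}"
            )
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path.name} line 2: malformed dimension line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ValueError(f"{path.name} line 2: malformed dimension line") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0)
    # GCT column 2 is Description; drop it
    if df.shape[1] == n_samples + 1:
        df = df.drop(columns=df.columns[0])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path.name}: dimension line says {n_genes}x{n_samples}, "
            f"table is {df.shape[0]}x{df.shape[1]}"
        )
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path.name}: {dups[:10]}")
    return df


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", matrix.gene_ids)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        sep = "," if format == "csv" else "\t"
        matrix.values.to_csv(path, sep=sep)


def read_sample_table(
    path,
    sample_col: str,
    class_col: str,
    subtype_col: Optional[str] = None,
    sep: Optional[str] = None,
) -> list[SampleAnnotation]:
    """Read sample annotations; rows with an empty class label are dropped."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in filter(None, (sample_col, class_col, subtype_col)):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not in {path.name}; available: {list(df.columns)}"
            )
    empty = df[class_col].isna() | (df[class_col].astype(str).str.strip() == "")
    if empty.any():
        warnings.warn(f"dropped {int(empty.sum())} rows with empty class label")
        df = df[~empty]
    if df[sample_col].duplicated().any():
        dups = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"repeated sample ids: {dups[:10]}")
    records = []
    for _, row in df.iterrows():
        sub = None
        if subtype_col is not None:
            v = row[subtype_col]
            sub = None if pd.isna(v) or str(v).strip() == "" else str(v)
        records.append(SampleAnnotation(str(row[sample_col]), str(row[class_col]), sub))
    return records


def read_ortholog_map(path, sep: str = "\t") -> OrthologMap:
    """Two-column (source_gene, target_gene) table with header."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (source_gene, target_gene)")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return OrthologMap(pairs)


# -- model bundles -------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a trained model (classifier, subtype or GRN bundle) to one file."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "kind": type(model).__name__,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load a bundle written by :func:`save_model`."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a bundle
        raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an oncopair model bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {payload['format_version']} unsupported "
            f"(this build reads version {BUNDLE_FORMAT_VERSION})"
        )
    return payload["model"]
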