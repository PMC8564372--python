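"""TSV/CSV/JSON readers and writers for every pipeline artifact.

Matrices travel as a values TSV (rows = genes, columns = sample ids)
with a sample-metadata sidecar TSV (sample_id, clutch, treatment,
time_h, assay); Ct tables as long-format TSV.  All files are UTF-8,
tab-delimited, '.' decimal; floats round-trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rarobust.containers import METADATA_COLUMNS, CtTable, ExpressionMatrix


def write_expression(
    matrix: ExpressionMatrix, values_path: str | Path, metadata_path: str | Path
) -> None:
    values_path, metadata_path = Path(values_path), Path(metadata_path)
    values_path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(values_path, sep="\t")
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta = meta.assign(scale=matrix.scale)
    meta.to_csv(metadata_path, sep="\t")


def read_expression(
    values_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    if values.empty and values.shape[1] == 0:
        raise ValueError(f"empty expression file: {values_path}")
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric value column(s): {non_numeric[:5]}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    scale = "log2"
    if "scale" in meta.columns:
        scales = meta["scale"].unique()
        if len(scales) != 1:
            raise ValueError(f"inconsistent scale labels in metadata: {scales}")
        scale = scales[0]
        meta = meta.drop(columns="scale")
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing for sample(s): {missing.tolist()[:5]}")
    return ExpressionMatrix(values, meta, scale)


def write_ct_table(ct: CtTable, records_path: str | Path, metadata_path: str | Path) -> None:
    records_path = Path(records_path)
    records_path.parent.mkdir(parents=True, exist_ok=True)
    ct.records.to_csv(records_path, sep="\t", index=False)
    meta = ct.samples.copy()
    meta.index.name = "sample_id"
    meta = meta.assign(housekeeping=ct.housekeeping)
    meta.to_csv(metadata_path, sep="\t")


def read_ct_table(records_path: str | Path, metadata_path: str | Path) -> CtTable:
    records = pd.read_csv(records_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    housekeeping = "gapdh"
    if "housekeeping" in meta.columns:
        housekeeping = meta["housekeeping"].iloc[0]
        meta = meta.drop(columns="housekeeping")
    return CtTable(records=records, samples=meta, housekeeping=housekeeping)


def write_frame(frame: pd.DataFrame, path: str | Path, index: bool = True, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=index)


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    ids = [line.strip() for line in text.splitlines() if line.strip()]
    if not ids:
        raise ValueError(f"empty gene list file: {path}")
    return ids


def write_gene_list(gene_ids, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(gene_ids) + ("\n" if len(list(gene_ids)) else ""))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def write_json(data: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n")
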