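"""File formats and report serialization.

Matrices are read/written as MatrixMarket triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecars (the 10x convention, genes as rows) or as dense
CSV/TSV with gene rows and a header of cell ids.  Cluster labels come from a
two-column TSV.  Attack results serialize to JSON (with a schema version and
the run configuration echoed for replayability); survey grids additionally to
CSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from .data_model import ClusterLabeling, ExpressionMatrix, validate_matrix

SCHEMA_VERSION = 1

_HEADER_CELL_WORDS = {"cell", "cell_id", "barcode", "cellid"}
_HEADER_LABEL_WORDS = {"cluster", "label", "cell_type", "celltype"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer matrix format from {path.name!r}")


def _read_id_column(path: Path) -> list[str]:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.empty:
        raise ValueError(f"empty identifier file: {path}")
    return frame.iloc[:, 0].tolist()


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix; sparse MatrixMarket input stays sparse.

    ``transpose`` flips cells-as-rows dialects into the canonical genes x
    cells orientation.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        values = sp.csr_matrix(spio.mmread(path))
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        if transpose:
            values = values.T.tocsr()
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {values.shape} but sidecars list "
                f"{len(gene_ids)} genes and {len(cell_ids)} cells"
            )
        matrix = ExpressionMatrix(values, gene_ids, cell_ids)
    elif fmt in ("csv", "tsv"):
        frame = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        if frame.empty:
            raise ValueError(f"empty matrix file: {path}")
        if transpose:
            frame = frame.T
        matrix = ExpressionMatrix(
            frame.to_numpy(dtype=float),
            [str(g) for g in frame.index],
            [str(c) for c in frame.columns],
        )
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    violations = validate_matrix(matrix)
    if violations:
        raise ValueError("invalid matrix: " + "; ".join(violations))
    return matrix


def write_matrix(matrix: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        values = matrix.values if matrix.is_sparse else sp.csr_matrix(matrix.values)
        spio.mmwrite(path, values)
        pd.Series(matrix.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(matrix.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
    elif fmt in ("csv", "tsv"):
        frame = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
        frame.to_csv(path, sep="," if fmt == "csv" else "\t")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_labels(path: str | Path, matrix: ExpressionMatrix | None = None) -> ClusterLabeling:
    """Two-column TSV (cell id, cluster label), header optional.

    With ``matrix`` given, cells of the matrix missing from the table raise;
    extra label rows are ignored with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"label file needs two columns (cell, cluster): {path}")
    first = [str(v).strip().lower() for v in frame.iloc[0, :2]]
    if first[0] in _HEADER_CELL_WORDS or first[1] in _HEADER_LABEL_WORDS:
        frame = frame.iloc[1:]
    labeling = ClusterLabeling(dict(zip(frame.iloc[:, 0], frame.iloc[:, 1])))
    if matrix is not None:
        missing = [c for c in matrix.cell_ids if c not in labeling.assignment]
        if missing:
            raise ValueError(
                f"{len(missing)} matrix cells have no cluster label, e.g. {missing[:5]}"
            )
        extra = set(labeling.assignment) - set(matrix.cell_ids)
        if extra:
            warnings.warn(
                f"{len(extra)} label rows do not match any matrix cell; ignored",
                stacklevel=2,
            )
            labeling = ClusterLabeling(
                {c: l for c, l in labeling.assignment.items() if c in matrix._cell_index}
            )
    return labeling


def write_labels(labeling: ClusterLabeling, path: str | Path) -> None:
    pd.DataFrame(
        {"cell": list(labeling.assignment), "cluster": list(labeling.assignment.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


def _to_jsonable(obj):
    if isinstance(obj, ExpressionMatrix):
        return {"n_genes": obj.n_genes, "n_cells": obj.n_cells}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(map(str, obj))
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if callable(obj):
        return getattr(obj, "__name__", "callable")
    return obj


def write_report(
    result,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Serialize any attack result to JSON; returns the written payload.

    The report embeds a schema version, the seed and a config echo so a run
    can be replayed exactly from its own output.
    """
    # dataclasses.asdict chokes on DataFrame/matrix fields; convert field-wise
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        body = {
            f.name: _to_jsonable(getattr(result, f.name))
            for f in dataclasses.fields(result)
            if not f.name.startswith("_")
        }
        kind = type(result).__name__
    else:
        body = _to_jsonable(result)
        kind = type(result).__name__
    payload = {
        "schema_version": SCHEMA_VERSION,
        "result_type": kind,
        "seed": seed,
        "config": _to_jsonable(config or {}),
        "result": body,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return payload


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
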