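"""File formats: TSV/CSV and Matrix Market round-tripping for all matrices.

Conventions:

* Expression matrices: TSV with a header row of gene labels and the
  first column holding cell labels; or Matrix Market (``.mtx``) with
  ``<stem>.cells.txt`` / ``<stem>.genes.txt`` label sidecars (one label
  per line) and an optional ``<stem>.celltypes.txt``.
* Pool designs: wide CSV (pools x cells, 0/1 entries, labelled), long
  CSV (``pool_id,cell_id`` membership rows), or Matrix Market.
* Pooled measurements: TSV (pools x genes) plus a JSON sidecar
  (``<path>.meta.json``) recording the normalized flag, turbulence,
  seed, and a hash of the design used.

Values are written with ``%.17g`` formatting and re-read with
round-trip float parsing, so a write/read cycle reproduces float64
values bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .compress import PoolMatrix
from .containers import ExpressionMatrix
from .design import MeasurementMatrix, export_pool_design, import_pool_design

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_pools",
    "write_pools",
    "design_hash",
]


def design_hash(values: np.ndarray) -> str:
    """Stable hex digest of a design's binary pattern."""
    arr = np.ascontiguousarray(np.asarray(values, dtype=np.uint8))
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def _natural_key(label: str):
    """Sort key treating digit runs numerically: cell_2 < cell_10."""
    parts = re.split(r"(\d+)", str(label))
    return [int(p) if p.isdigit() else p for p in parts]


def _read_labels(path: Path) -> list[str]:
    return path.read_text().splitlines()


def _write_labels(path: Path, labels) -> None:
    path.write_text("\n".join(str(x) for x in labels) + "\n")


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV/CSV or Matrix Market (by suffix)."""
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(em.values))
        _write_labels(_sidecar(path, ".cells.txt"), em.cell_labels)
        _write_labels(_sidecar(path, ".genes.txt"), em.gene_labels)
        if em.cell_types is not None:
            _write_labels(_sidecar(path, ".celltypes.txt"), em.cell_types)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        # %.17g guarantees bit-exact float64 round-trips through text
        em.to_frame().to_csv(
            path, sep=sep, index_label="cell_id", float_format="%.17g"
        )
        if em.cell_types is not None:
            _write_labels(_sidecar(path, ".celltypes.txt"), em.cell_types)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression`."""
    path = Path(path)
    if path.suffix == ".mtx":
        values = np.asarray(spio.mmread(str(path)).todense(), dtype=float)
        cells = _read_labels(_sidecar(path, ".cells.txt"))
        genes = _read_labels(_sidecar(path, ".genes.txt"))
        types_path = _sidecar(path, ".celltypes.txt")
        types = np.array(_read_labels(types_path)) if types_path.exists() else None
        return ExpressionMatrix(
            values=values, cell_labels=cells, gene_labels=genes, cell_types=types
        )
    sep = "," if path.suffix == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    types_path = _sidecar(path, ".celltypes.txt")
    types = np.array(_read_labels(types_path)) if types_path.exists() else None
    return ExpressionMatrix.from_frame(df, cell_types=types)


def write_design(
    M: MeasurementMatrix,
    path: str | Path,
    cell_labels: list[str] | None = None,
    layout: str = "wide",
) -> None:
    """Write a pool design.

    ``layout='wide'`` writes a labelled 0/1 matrix CSV (pools as rows);
    ``layout='long'`` writes the two-column membership table; an
    ``.mtx`` suffix writes sparse Matrix Market with label sidecars.
    """
    path = Path(path)
    n_pools, n_cells = M.shape
    if cell_labels is None:
        cell_labels = [f"cell_{j}" for j in range(n_cells)]
    pool_labels = [f"pool_{i}" for i in range(n_pools)]
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(M.values))
        _write_labels(_sidecar(path, ".pools.txt"), pool_labels)
        _write_labels(_sidecar(path, ".cells.txt"), cell_labels)
    elif layout == "long":
        export_pool_design(M, cell_labels, pool_labels).to_csv(path, index=False)
    else:
        df = pd.DataFrame(
            M.values.astype(int), index=pool_labels, columns=cell_labels
        )
        df.to_csv(path, index_label="pool_id")


def read_design(path: str | Path) -> tuple[MeasurementMatrix, list[str], list[str]]:
    """Read a design in any layout; returns (design, pool_labels, cell_labels)."""
    path = Path(path)
    if path.suffix == ".mtx":
        values = np.asarray(spio.mmread(str(path)).todense(), dtype=float)
        pools = _read_labels(_sidecar(path, ".pools.txt"))
        cells = _read_labels(_sidecar(path, ".cells.txt"))
        return MeasurementMatrix(values=values), pools, cells
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed design file {path}: {exc}") from exc
    if list(df.columns[:2]) == ["pool_id", "cell_id"] and df.shape[1] == 2:
        # membership rows carry no column order; natural-sorted labels
        # reproduce the conventional pool_i / cell_j orderings
        pools = sorted(set(df["pool_id"]), key=_natural_key)
        cells = sorted(set(df["cell_id"]), key=_natural_key)
        return import_pool_design(df, cell_labels=cells, pool_labels=pools)
    df = df.set_index(df.columns[0])
    return (
        MeasurementMatrix(values=df.to_numpy(dtype=float)),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_pools(
    Y: PoolMatrix,
    path: str | Path,
    turbulence: float = 0.0,
    seed: int | None = None,
    design: MeasurementMatrix | np.ndarray | None = None,
) -> None:
    """Write pooled measurements as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.DataFrame(Y.values, index=Y.pool_labels, columns=Y.gene_labels)
    df.to_csv(path, sep=sep, index_label="pool_id", float_format="%.17g")
    meta = {
        "normalized": bool(Y.normalized),
        "turbulence": turbulence,
        "seed": seed,
        "design_hash": None,
    }
    if design is not None:
        values = design.values if hasattr(design, "values") else design
        meta["design_hash"] = design_hash(values)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_pools(path: str | Path) -> tuple[PoolMatrix, dict]:
    """Read pooled measurements and their metadata sidecar (if present)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed pool file {path}: {exc}") from exc
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    Y = PoolMatrix(
        values=df.to_numpy(dtype=float),
        normalized=bool(meta.get("normalized", False)),
        pool_labels=[str(i) for i in df.index],
        gene_labels=[str(c) for c in df.columns],
    )
    return Y, meta
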