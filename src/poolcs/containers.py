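"""Core in-memory containers shared across the package.

The central object is the single-cell expression profile (SCEP): a
``cells x genes`` matrix of nonnegative, TPM-scale values.  Note the
orientation — cells are rows — which is the transpose of the classic
genes-by-cells layout, because the pooling model compresses along the
cell axis: each gene column is an independent signal of length
``n_cells`` observed through the pool design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "as_expression_matrix"]


def _default_labels(prefix: str, n: int) -> list[str]:
    width = max(1, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass
class ExpressionMatrix:
    """A cells x genes nonnegative expression matrix with labels.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array of nonnegative reals (TPM scale).
    cell_labels, gene_labels
        Row / column labels; generated if omitted.
    cell_types
        Optional per-cell type assignment (length ``n_cells``).
    """

    values: np.ndarray
    cell_labels: list[str] = field(default_factory=list)
    gene_labels: list[str] = field(default_factory=list)
    cell_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"expression matrix must be 2-D, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        n_cells, n_genes = self.values.shape
        if not self.cell_labels:
            self.cell_labels = _default_labels("cell_", n_cells)
        if not self.gene_labels:
            self.gene_labels = _default_labels("gene_", n_genes)
        if len(self.cell_labels) != n_cells:
            raise ValueError(
                f"{len(self.cell_labels)} cell labels for {n_cells} cells"
            )
        if len(self.gene_labels) != n_genes:
            raise ValueError(
                f"{len(self.gene_labels)} gene labels for {n_genes} genes"
            )
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types)
            if self.cell_types.shape != (n_cells,):
                raise ValueError("cell_types must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_labels, columns=self.gene_labels
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, cell_types: np.ndarray | None = None
    ) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            cell_labels=[str(c) for c in df.index],
            gene_labels=[str(g) for g in df.columns],
            cell_types=cell_types,
        )


def as_expression_matrix(X) -> ExpressionMatrix:
    """Coerce an array / DataFrame / ExpressionMatrix to ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_frame(X)
    return ExpressionMatrix(values=np.asarray(X, dtype=float))
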