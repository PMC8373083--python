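"""Forward model: pooled measurements from an expression matrix.

Pooling is linear: with design ``M`` (pools x cells) and SCEP ``X``
(cells x genes), the pooled observation is ``Y = M @ X`` (pools x
genes).  Two refinements model the wet lab:

* **turbulence** — pipetting error, sample degradation and sequencing
  noise act on the cells actually added to a pool, so each design entry
  1 is replaced by a uniform draw from the open interval ``(1-t, 1+t)``
  before measuring; zeros (cells absent from the pool) are untouched.
* **TPM mode** — pooled libraries are sequenced to one depth shared by
  all member cells, so each TPM-normalized pool row is the *average*
  (not the sum) of its member cells: ``Y_tpm = diag(1/rowsum(M)) M X``.

Reconstruction always receives the nominal design (binary, or
row-normalized in TPM mode); only the measurements see turbulence.
That mismatch is exactly how noise degrades recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import as_expression_matrix
from .design import MeasurementMatrix, normalize_rows

__all__ = [
    "PerturbedMeasurementMatrix",
    "PoolMatrix",
    "perturb_design",
    "measure",
    "measure_tpm",
]


@dataclass
class PerturbedMeasurementMatrix:
    """A design whose ones were replaced by uniform draws from (1-t, 1+t)."""

    values: np.ndarray
    turbulence: float
    seed: int | None
    source: MeasurementMatrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PoolMatrix:
    """Pools x genes measurement matrix, optionally TPM-normalized."""

    values: np.ndarray
    normalized: bool = False
    pool_labels: list[str] = field(default_factory=list)
    gene_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"pool matrix must be 2-D, got {self.values.shape}")
        n_pools, n_genes = self.values.shape
        if not self.pool_labels:
            self.pool_labels = [f"pool_{i}" for i in range(n_pools)]
        if not self.gene_labels:
            self.gene_labels = [f"gene_{j}" for j in range(n_genes)]

    @property
    def n_pools(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def perturb_design(
    M: MeasurementMatrix, t: float, seed: int | None = None
) -> PerturbedMeasurementMatrix:
    """Replace each 1 in the design with a uniform draw from ``(1-t, 1+t)``.

    ``t = 0`` returns the design unchanged.  Draws landing exactly on an
    interval endpoint are redrawn so perturbed entries are strictly
    interior (practically a measure-zero event, handled for strictness
    of the support contract).
    """
    if not 0 <= t < 1:
        raise ValueError(f"turbulence must be in [0, 1), got {t}")
    values = M.values.copy()
    lo, hi = 1.0 - t, 1.0 + t
    if t > 0 and lo < 1.0 < hi:  # interval degenerate below float precision -> no-op
        rng = np.random.default_rng(seed)
        ones = M.values == 1.0
        n_ones = int(ones.sum())
        draws = rng.uniform(lo, hi, size=n_ones)
        # redraw exact endpoint hits so entries are strictly interior
        bad = (draws <= lo) | (draws >= hi)
        while bad.any():  # pragma: no cover - endpoint draws are measure-zero
            draws[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
            bad = (draws <= lo) | (draws >= hi)
        values[ones] = draws
    return PerturbedMeasurementMatrix(
        values=values, turbulence=t, seed=seed, source=M
    )


def _design_values(design) -> np.ndarray:
    if isinstance(design, (MeasurementMatrix, PerturbedMeasurementMatrix)):
        return design.values
    return np.asarray(design, dtype=float)


def measure(design, X) -> PoolMatrix:
    """Exact pooled measurements ``Y = M @ X`` (raw pool sums)."""
    em = as_expression_matrix(X)
    values = _design_values(design)
    if values.shape[1] != em.n_cells:
        raise ValueError(
            f"design has {values.shape[1]} cell columns but expression "
            f"matrix has {em.n_cells} cells (design shape {values.shape}, "
            f"expression shape {em.shape})"
        )
    return PoolMatrix(
        values=values @ em.values,
        normalized=False,
        gene_labels=list(em.gene_labels),
    )


def measure_tpm(M: MeasurementMatrix, X_tpm) -> PoolMatrix:
    """Depth-shared pooled measurements ``diag(1/rowsum(M)) M X``.

    Models the wet-lab path where the cells of a pool equally share its
    sequencing depth, so each pool row is the mean of its member cells'
    TPM rows.  Identical to ``measure(normalize_rows(M), X)``.
    """
    em = as_expression_matrix(X_tpm)
    normalized = normalize_rows(M)
    if normalized.shape[1] != em.n_cells:
        raise ValueError(
            f"design has {normalized.shape[1]} cell columns but expression "
            f"matrix has {em.n_cells} cells"
        )
    return PoolMatrix(
        values=normalized @ em.values,
        normalized=True,
        gene_labels=list(em.gene_labels),
    )
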