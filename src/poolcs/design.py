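"""Overlapped pool designs (measurement matrices).

A pool design is a binary ``pools x cells`` matrix M with
``m_ij = 1`` iff pool *i* receives an aliquot of cell *j*'s cDNA.
Random Bernoulli designs — each entry independently 1 with probability
``inclusion_prob`` — are the standard measurement matrices of compressed
sensing: with high probability they satisfy the restricted isometry
property once the number of pools exceeds ``c * K * log(N / K)`` for
K-sparse signals of length N.

Every cell must land in at least one pool (an unpooled cell is
unrecoverable) and every pool must contain at least one cell (an empty
pool wastes a sequencing library), so generation resamples until both
hold, within a bounded retry budget.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementMatrix",
    "generate_measurement_matrix",
    "required_pool_count",
    "normalize_rows",
    "validate_measurement_matrix",
    "export_pool_design",
    "import_pool_design",
]


@dataclass
class MeasurementMatrix:
    """Binary pools x cells design matrix.

    Attributes
    ----------
    values
        ``(n_pools, n_cells)`` array of {0, 1} floats.
    inclusion_prob
        Probability with which each entry was set to 1 (None when the
        matrix was imported rather than generated).
    seed
        Seed used for generation, when known.
    """

    values: np.ndarray
    inclusion_prob: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        validate_measurement_matrix(self.values)

    @property
    def n_pools(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def validate_measurement_matrix(values: np.ndarray) -> None:
    """Check binaryness and coverage; warn on unidentifiable columns.

    Duplicate or all-zero columns make the corresponding cells
    indistinguishable to any decoder, but random designs can rarely
    collide, so this is a warning rather than an error.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"design must be 2-D, got shape {values.shape}")
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("design entries must all be 0 or 1")
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        bad = np.flatnonzero(row_sums == 0)
        raise ValueError(f"pool(s) {bad.tolist()} contain no cells")
    col_sums = values.sum(axis=0)
    if np.any(col_sums == 0):
        bad = np.flatnonzero(col_sums == 0)
        raise ValueError(f"cell(s) {bad.tolist()} appear in no pool")
    # column collisions: duplicated pool-membership patterns
    _, counts = np.unique(values, axis=1, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(
            "design has duplicate columns; the corresponding cells are "
            "indistinguishable from their pooled measurements",
            stacklevel=3,
        )


def generate_measurement_matrix(
    n_pools: int,
    n_cells: int,
    inclusion_prob: float = 0.5,
    seed: int | None = None,
    max_retries: int = 1000,
) -> MeasurementMatrix:
    """Draw a random Bernoulli pool design.

    Each of the ``n_pools * n_cells`` entries is independently 1 with
    probability ``inclusion_prob`` (default 0.5, the standard symmetric
    Bernoulli ensemble; 0.3 is a sparser preset that eases bench work on
    very large cell numbers).  Draws with an empty pool or an unpooled
    cell are rejected and redrawn, up to ``max_retries`` times.

    Raises
    ------
    RuntimeError
        If no valid matrix is found within the retry budget (e.g. an
        ``inclusion_prob`` so small that empty pools are near-certain).
    """
    if n_pools < 1 or n_cells < 1:
        raise ValueError("n_pools and n_cells must be positive")
    if not 0 < inclusion_prob <= 1:
        raise ValueError(f"inclusion_prob must be in (0, 1], got {inclusion_prob}")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries + 1):
        values = (rng.random((n_pools, n_cells)) < inclusion_prob).astype(float)
        if values.sum(axis=1).min() > 0 and values.sum(axis=0).min() > 0:
            if attempt:
                logger.info(
                    "pool design accepted after %d rejected draw(s)", attempt
                )
            return MeasurementMatrix(
                values=values, inclusion_prob=inclusion_prob, seed=seed
            )
        logger.debug(
            "retry %d: design %dx%d had an empty pool or unpooled cell",
            attempt + 1,
            n_pools,
            n_cells,
        )
    raise RuntimeError(
        f"no valid {n_pools}x{n_cells} design with inclusion_prob="
        f"{inclusion_prob} found in {max_retries} retries; "
        "increase inclusion_prob or the retry budget"
    )


_LOG_FNS = {
    "natural": math.log,
    "base10": math.log10,
    "base2": math.log2,
}


def required_pool_count(
    K: int,
    N: int,
    c_const: float = 1.0,
    log_base: str = "natural",
) -> int:
    """Advisory pool count from the RIP heuristic ``ceil(c*K*log(N/K))``.

    ``K`` is the sparsity (nonzeros per gene column), ``N`` the signal
    length (number of cells).  The constant ``c_const`` and the log base
    are deliberately explicit parameters: the heuristic only fixes the
    scaling, not the constants.  Purely advisory — it never gates design
    generation.
    """
    if K < 1 or N < 1:
        raise ValueError("K and N must be positive")
    if K > N:
        raise ValueError(f"sparsity K={K} cannot exceed signal length N={N}")
    if c_const <= 0:
        raise ValueError("c_const must be positive")
    try:
        log = _LOG_FNS[log_base]
    except KeyError:
        raise ValueError(
            f"log_base must be one of {sorted(_LOG_FNS)}, got {log_base!r}"
        ) from None
    if K == N:
        return 0
    return math.ceil(c_const * K * log(N / K))


def normalize_rows(M: MeasurementMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic version of a design: ``diag(1/rowsum(M)) @ M``.

    Models pooled sequencing depth being shared equally by the cells in
    a pool.  The zero pattern is preserved and every row sums to 1.
    """
    values = M.values if isinstance(M, MeasurementMatrix) else np.asarray(M, float)
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        bad = np.flatnonzero(row_sums == 0)
        raise ValueError(f"cannot normalize: pool(s) {bad.tolist()} are empty")
    return values / row_sums[:, None]


def export_pool_design(
    M: MeasurementMatrix | np.ndarray,
    cell_labels: list[str] | None = None,
    pool_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format membership table: one row per (pool, cell) membership.

    Columns are ``pool_id`` and ``cell_id``; the total row count equals
    the number of ones in the design.  Round-trips losslessly through
    :func:`import_pool_design`.
    """
    values = M.values if isinstance(M, MeasurementMatrix) else np.asarray(M, float)
    n_pools, n_cells = values.shape
    if cell_labels is None:
        cell_labels = [f"cell_{j}" for j in range(n_cells)]
    if len(cell_labels) != n_cells:
        raise ValueError(
            f"{len(cell_labels)} cell labels for a design with {n_cells} cells"
        )
    if pool_labels is None:
        pool_labels = [f"pool_{i}" for i in range(n_pools)]
    if len(pool_labels) != n_pools:
        raise ValueError(
            f"{len(pool_labels)} pool labels for a design with {n_pools} pools"
        )
    rows_idx, cols_idx = np.nonzero(values)
    return pd.DataFrame(
        {
            "pool_id": [pool_labels[i] for i in rows_idx],
            "cell_id": [cell_labels[j] for j in cols_idx],
        }
    )


def import_pool_design(
    table: pd.DataFrame,
    cell_labels: list[str] | None = None,
    pool_labels: list[str] | None = None,
) -> tuple[MeasurementMatrix, list[str], list[str]]:
    """Rebuild a design from a long-format membership table.

    Label orderings default to first-appearance order in the table;
    passing the original orderings reproduces the source matrix exactly.
    Returns ``(design, pool_labels, cell_labels)``.
    """
    for col in ("pool_id", "cell_id"):
        if col not in table.columns:
            raise ValueError(f"membership table lacks required column {col!r}")
    if pool_labels is None:
        pool_labels = list(dict.fromkeys(table["pool_id"]))
    if cell_labels is None:
        cell_labels = list(dict.fromkeys(table["cell_id"]))
    pool_index = {p: i for i, p in enumerate(pool_labels)}
    cell_index = {c: j for j, c in enumerate(cell_labels)}
    values = np.zeros((len(pool_labels), len(cell_labels)))
    for pool, cell in zip(table["pool_id"], table["cell_id"]):
        try:
            values[pool_index[pool], cell_index[cell]] = 1.0
        except KeyError as exc:
            raise ValueError(f"membership refers to unknown label {exc}") from None
    return (
        MeasurementMatrix(values=values),
        list(pool_labels),
        list(cell_labels),
    )
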