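"""Synthetic single-cell expression profiles (SCEPs).

Real plate-based SCEPs are zero-inflated: a pancreatic-islet style
dataset with strong cell-type structure can have only ~24.5% non-zero
entries ("high sparsity"), while a T-lymphocyte style dataset of closely
related cells sits around ~32.3% ("low sparsity").  This generator
emulates those regimes parametrically so the compression / recovery
pipeline can be exercised at any scale without external data.

The model:

* cells are assigned to ``n_types`` balanced types;
* a ``marker_frac`` fraction of genes are type-specific markers with a
  high expression probability in their own type and a low one elsewhere;
  the remaining genes split into a housekeeping-like stratum expressed
  in most cells and a Beta-distributed long tail of rarely expressed
  genes, matching the bimodal gene sparsity-level profile of plate-based
  data (and giving unrelated cells the baseline correlation real SCEPs
  show);
* all expression probabilities are rescaled by a single multiplier
  (found by bisection, with clipping at 1) so the expected non-zero
  fraction equals ``target_nonzero_frac`` exactly;
* expressed entries draw gamma-distributed positive values — a
  heavy-tailed, negative-binomial-like magnitude model on the TPM
  scale — with marker genes upregulated in their own type, and each
  gene's mean magnitude proportional to its expression probability:
  in real data detection probability rises with mean expression (the
  dropout-mean relationship), so the highest-expression genes are the
  dense, near-ubiquitous ones.

Same-type cells therefore share both support and magnitude structure,
so within-type correlation exceeds between-type correlation, the
property that makes the signal compressible in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .containers import ExpressionMatrix, as_expression_matrix

__all__ = [
    "SyntheticProfileSpec",
    "simulate_scep",
    "gene_sparsity_profile",
    "SparsityProfile",
    "HIGH_SPARSITY_NONZERO_FRAC",
    "LOW_SPARSITY_NONZERO_FRAC",
]

# the two reference sparsity regimes (fraction of non-zero entries)
HIGH_SPARSITY_NONZERO_FRAC = 0.2449
LOW_SPARSITY_NONZERO_FRAC = 0.3230


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Parameters of the synthetic SCEP generator.

    ``target_nonzero_frac`` is the expected fraction of non-zero entries
    in the whole matrix; ``marker_frac`` the fraction of genes that are
    type-specific markers; ``dispersion`` the gamma shape of expressed
    magnitudes (smaller = heavier tail); ``mean_expression`` the
    TPM-scale baseline of expressed magnitudes (gene means are this
    baseline times the gene's expression probability times a lognormal
    spread).
    """

    n_cells: int = 64
    n_genes: int = 2000
    target_nonzero_frac: float = HIGH_SPARSITY_NONZERO_FRAC
    n_types: int = 7
    marker_frac: float = 0.3
    dispersion: float = 1.5
    mean_expression: float = 200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if not 0 < self.target_nonzero_frac <= 1:
            raise ValueError(
                f"target_nonzero_frac must be in (0, 1], got "
                f"{self.target_nonzero_frac}"
            )
        if self.n_types < 1:
            raise ValueError("n_types must be positive")
        if self.n_types > self.n_cells:
            raise ValueError(
                f"n_types={self.n_types} exceeds n_cells={self.n_cells}"
            )
        if not 0 <= self.marker_frac <= 1:
            raise ValueError(f"marker_frac must be in [0, 1], got {self.marker_frac}")
        if self.marker_frac > 0 and self.n_types > self.n_genes:
            raise ValueError(
                "marker genes requested but n_types exceeds n_genes; "
                "no type can receive a marker"
            )
        if self.dispersion <= 0 or self.mean_expression <= 0:
            raise ValueError("dispersion and mean_expression must be positive")


# baseline (pre-calibration) expression probabilities
_MARKER_ON = 0.85   # marker gene in its own type
_MARKER_OFF = 0.05  # marker gene in other types
_HK_FRAC = 0.4      # housekeeping share of the non-marker genes
_HK_RANGE = (0.7, 0.98)    # expression prob of a housekeeping gene
_RARE_BETA = (0.45, 2.2)   # expression prob of the rare-gene tail
_MARKER_FOLD = 4.0  # magnitude upregulation of a marker in its own type
_GENE_MEAN_SIGMA = 1.8  # lognormal spread of gene mean expression
_DENSITY_COUPLING = 1.0  # exponent tying gene mean to expression probability


def _calibrate_probs(base: np.ndarray, target: float) -> np.ndarray:
    """Scale probabilities (with clipping at 1) to hit a mean of ``target``.

    ``mean(min(s * base, 1))`` is continuous and nondecreasing in s,
    equals 0 at s=0 and 1 for large s (all base probs are > 0), so
    bisection always converges.
    """
    if target >= 1.0:
        return np.ones_like(base)

    def realized(s: float) -> float:
        return float(np.minimum(s * base, 1.0).mean())

    lo, hi = 0.0, 1.0
    while realized(hi) < target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - base floored well above 0
            raise RuntimeError("probability calibration failed to bracket target")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * base, 1.0)


def simulate_scep(spec: SyntheticProfileSpec) -> ExpressionMatrix:
    """Generate a synthetic SCEP under ``spec``; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    n_cells, n_genes = spec.n_cells, spec.n_genes

    cell_types = np.arange(n_cells) % spec.n_types
    n_markers = int(round(spec.marker_frac * n_genes))
    marker_type = np.full(n_genes, -1)  # -1 = shared gene
    if n_markers:
        marker_type[:n_markers] = np.arange(n_markers) % spec.n_types

    # baseline expression probability per (cell, gene): housekeeping
    # stratum + rare tail for shared genes, on/off split for markers
    base = np.empty((n_cells, n_genes))
    n_shared = n_genes - n_markers
    is_hk = rng.random(n_shared) < _HK_FRAC
    shared_prob = np.where(
        is_hk,
        rng.uniform(*_HK_RANGE, size=n_shared),
        np.clip(rng.beta(*_RARE_BETA, size=n_shared), 1e-3, 1.0),
    )
    base[:, n_markers:] = shared_prob[None, :]
    if n_markers:
        marker_cols = marker_type[:n_markers]
        own = cell_types[:, None] == marker_cols[None, :]
        base[:, :n_markers] = np.where(own, _MARKER_ON, _MARKER_OFF)

    probs = _calibrate_probs(base, spec.target_nonzero_frac)
    mask = rng.random((n_cells, n_genes)) < probs

    # magnitudes: gene-level lognormal mean coupled to gene density
    # (dropout-mean relationship), marker upregulation, gamma noise
    sigma = _GENE_MEAN_SIGMA
    gene_density = probs.mean(axis=0)
    gene_mean = (
        spec.mean_expression
        * gene_density**_DENSITY_COUPLING
        * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_genes)
    )
    mu = np.broadcast_to(gene_mean, (n_cells, n_genes)).copy()
    if n_markers:
        mu[:, :n_markers] = np.where(
            own, _MARKER_FOLD * mu[:, :n_markers], mu[:, :n_markers]
        )
    values = mask * rng.gamma(
        shape=spec.dispersion, scale=mu / spec.dispersion, size=(n_cells, n_genes)
    )
    # a masked-in entry should register as expressed even if the gamma
    # draw underflows to zero (possible for tiny shape parameters)
    tiny = values[mask & (values <= 0)]
    if tiny.size:
        values[mask & (values <= 0)] = np.finfo(float).tiny

    type_names = np.array([f"type_{t}" for t in range(spec.n_types)])
    return ExpressionMatrix(
        values=values,
        cell_types=type_names[cell_types],
    )


class SparsityProfile(NamedTuple):
    """Per-gene expressing-cell counts plus the matrix-wide non-zero fraction."""

    expressing_cells: np.ndarray
    nonzero_fraction: float


def gene_sparsity_profile(X, zero_tol: float = 0.0) -> SparsityProfile:
    """Count, per gene, the cells expressing it above ``zero_tol``.

    A gene's *sparsity level* is inversely related to this count: the
    fewer cells a gene is expressed in, the higher its sparsity level.
    ``zero_tol`` defaults to 0 (exact zeros, as produced by the
    generator); use 0.001 for TPM data, where values below that are
    treated as unexpressed.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be nonnegative")
    em = as_expression_matrix(X)
    expressed = em.values > zero_tol
    counts = expressed.sum(axis=0)
    return SparsityProfile(
        expressing_cells=counts,
        nonzero_fraction=float(expressed.mean()),
    )
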