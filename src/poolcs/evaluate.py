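"""Reconstruction-quality metrics.

The headline metric is per-cell Pearson correlation: each recovered
cell row is correlated with its original row (``rho_c``), and the mean
over cells (``rho``) summarizes how consistent pooled decoding is with
per-cell sequencing.  Supporting metrics: a cells x cells correlation
matrix between original and inferred profiles (heat-map source), gene
detection sensitivity, per-gene correlation profiles stratified by
sparsity level or total expression (violin-plot source), and the
library-cost accounting (``n_cells - n_pools`` libraries saved).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, as_expression_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "cell_correlations",
    "cell_correlation_matrix",
    "detection_sensitivity",
    "DetectionResult",
    "gene_correlation_profile",
    "library_savings",
    "LibrarySavings",
    "evaluate_reconstruction",
]


def _paired(X, X_hat) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    em_x = X if isinstance(X, ExpressionMatrix) else as_expression_matrix(X)
    if isinstance(X_hat, ExpressionMatrix):
        em_h = X_hat
    else:
        # inferred matrices may contain negative solver output; bypass
        # the nonnegativity check of the standard container
        from .reconstruct import _RawExpressionMatrix

        em_h = _RawExpressionMatrix(values=np.asarray(X_hat, dtype=float))
    if em_x.shape != em_h.shape:
        raise ValueError(
            f"shape mismatch: original {em_x.shape} vs inferred {em_h.shape}"
        )
    return em_x, em_h


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of matched rows; NaN where either row is constant."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Ac * Bc).sum(axis=1) / (na * nb)
    rho[(na == 0) | (nb == 0)] = np.nan
    return rho


def cell_correlations(X, X_hat) -> tuple[np.ndarray, float]:
    """Per-cell Pearson correlations ``rho_c`` and their mean ``rho``.

    Cells whose row is constant (zero variance) in either matrix have an
    undefined correlation; they are reported as NaN and excluded from
    the mean, with a logged warning.
    """
    em_x, em_h = _paired(X, X_hat)
    rho_c = _row_correlations(em_x.values, em_h.values)
    n_undefined = int(np.isnan(rho_c).sum())
    if n_undefined:
        logger.warning(
            "%d cell(s) with zero variance excluded from mean correlation",
            n_undefined,
        )
    finite = rho_c[~np.isnan(rho_c)]
    mean_rho = float(finite.mean()) if finite.size else float("nan")
    return rho_c, mean_rho


def cell_correlation_matrix(X, X_hat) -> np.ndarray:
    """Cells x cells Pearson matrix: entry (i, j) correlates original
    cell i with inferred cell j.  The diagonal equals ``rho_c``."""
    em_x, em_h = _paired(X, X_hat)
    A = em_x.values - em_x.values.mean(axis=1, keepdims=True)
    B = em_h.values - em_h.values.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (A @ B.T) / np.outer(na, nb)
    return corr


class DetectionResult(NamedTuple):
    """Gene detection accounting between original and inferred profiles."""

    detected_original: int
    detected_inferred: int
    detection_fraction: float
    lost_high_expression: int


def detection_sensitivity(
    X, X_hat, detect_tol: float = 0.001, high_expr_threshold: float = 1.0
) -> DetectionResult:
    """Compare detected-gene counts between original and inferred SCEPs.

    A gene counts as detected when its total across cells is at least
    ``detect_tol`` (default 0.001, below which TPM values are treated
    as unexpressed).  ``lost_high_expression`` counts genes undetected
    in the inference whose original total exceeds
    ``high_expr_threshold`` — losses among clearly expressed genes.
    """
    if detect_tol < 0:
        raise ValueError("detect_tol must be nonnegative")
    em_x, em_h = _paired(X, X_hat)
    tot_x = em_x.values.sum(axis=0)
    tot_h = np.clip(em_h.values, 0.0, None).sum(axis=0)
    det_x = tot_x >= detect_tol
    det_h = tot_h >= detect_tol
    n_x = int(det_x.sum())
    n_h = int(det_h.sum())
    lost = det_x & ~det_h
    lost_high = int((lost & (tot_x > high_expr_threshold)).sum())
    fraction = n_h / n_x if n_x else float("nan")
    return DetectionResult(n_x, n_h, float(fraction), lost_high)


def gene_correlation_profile(
    X,
    X_hat,
    ranking: str = "sparsity_level",
    n_bins: int = 5,
    zero_tol: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene correlations grouped into quantile bins by a ranking.

    ``ranking='sparsity_level'`` orders genes from the sparsest (fewest
    expressing cells) to the densest; ``ranking='total_expression'``
    orders by ascending total expression.  Returns ``(per_gene,
    summary)``: per-gene correlation with its bin assignment, and
    per-bin median / quartiles (the numbers a violin plot would show).
    Genes constant in both matrices have undefined correlation and are
    excluded, with their count logged.
    """
    if ranking not in ("sparsity_level", "total_expression"):
        raise ValueError(
            "ranking must be 'sparsity_level' or 'total_expression', "
            f"got {ranking!r}"
        )
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    em_x, em_h = _paired(X, X_hat)
    corr = _row_correlations(em_x.values.T, em_h.values.T)
    expressing = (em_x.values > zero_tol).sum(axis=0)
    totals = em_x.values.sum(axis=0)
    per_gene = pd.DataFrame(
        {
            "gene": em_x.gene_labels,
            "correlation": corr,
            "expressing_cells": expressing,
            "total_expression": totals,
        }
    )
    n_excluded = int(per_gene["correlation"].isna().sum())
    if n_excluded:
        logger.info(
            "%d gene(s) with undefined correlation excluded from profile",
            n_excluded,
        )
    defined = per_gene.dropna(subset=["correlation"]).copy()
    if ranking == "sparsity_level":
        # sparsest genes (fewest expressing cells) come first
        key = defined["expressing_cells"]
    else:
        key = defined["total_expression"]
    order = key.rank(method="first")
    n_eff = min(n_bins, len(defined)) or 1
    defined["bin"] = pd.qcut(order, q=n_eff, labels=False)
    per_gene = per_gene.merge(defined[["gene", "bin"]], on="gene", how="left")
    summary = (
        defined.groupby("bin")["correlation"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n_genes="size",
        )
        .reset_index()
    )
    return per_gene, summary


class LibrarySavings(NamedTuple):
    """Sequencing libraries avoided by pooling."""

    libraries_saved: int
    savings_fraction_pct: float


def library_savings(n_cells: int, n_pools: int) -> LibrarySavings:
    """Libraries saved = ``max(n_cells - n_pools, 0)``; fraction of cells.

    Pooling 54 cells into 28 libraries saves 26 libraries, i.e. 48.15%
    of the per-cell library cost.  The percentage is rounded to two
    decimals.
    """
    if n_cells < 1 or n_pools < 1:
        raise ValueError("n_cells and n_pools must be positive")
    saved = max(n_cells - n_pools, 0)
    pct = round(100.0 * saved / n_cells, 2)
    return LibrarySavings(libraries_saved=saved, savings_fraction_pct=pct)


@dataclass
class EvaluationReport:
    """Bundle of all evaluation outputs for one reconstruction run."""

    per_cell_rho: np.ndarray
    mean_rho: float
    cell_by_cell_corr: np.ndarray
    gene_profile: pd.DataFrame
    gene_profile_summary: pd.DataFrame
    detection: DetectionResult
    savings: LibrarySavings
    cell_labels: list[str] = field(default_factory=list)

    def scalars(self) -> dict:
        return {
            "mean_rho": self.mean_rho,
            "median_rho": float(np.nanmedian(self.per_cell_rho)),
            "n_cells": int(self.per_cell_rho.size),
            "n_undefined_cells": int(np.isnan(self.per_cell_rho).sum()),
            "detected_original": self.detection.detected_original,
            "detected_inferred": self.detection.detected_inferred,
            "detection_fraction": self.detection.detection_fraction,
            "lost_high_expression": self.detection.lost_high_expression,
            "libraries_saved": self.savings.libraries_saved,
            "savings_fraction_pct": self.savings.savings_fraction_pct,
        }

    def to_json(self) -> str:
        return json.dumps(self.scalars(), indent=2, sort_keys=True)


def evaluate_reconstruction(
    X,
    X_hat,
    n_pools: int | None = None,
    detect_tol: float = 0.001,
    n_bins: int = 5,
    ranking: str = "sparsity_level",
) -> EvaluationReport:
    """Compute the full evaluation bundle for one reconstruction."""
    em_x, em_h = _paired(X, X_hat)
    rho_c, mean_rho = cell_correlations(em_x, em_h)
    corr_matrix = cell_correlation_matrix(em_x, em_h)
    per_gene, summary = gene_correlation_profile(
        em_x, em_h, ranking=ranking, n_bins=n_bins
    )
    detection = detection_sensitivity(em_x, em_h, detect_tol=detect_tol)
    savings = library_savings(
        em_x.n_cells, n_pools if n_pools is not None else em_x.n_cells
    )
    return EvaluationReport(
        per_cell_rho=rho_c,
        mean_rho=mean_rho,
        cell_by_cell_corr=corr_matrix,
        gene_profile=per_gene,
        gene_profile_summary=summary,
        detection=detection,
        savings=savings,
        cell_labels=list(em_x.cell_labels),
    )
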