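"""End-to-end pipeline: simulate → design → compress → decode → evaluate.

A single :class:`PipelineConfig` drives the whole chain.  One master
seed deterministically derives the per-stage seeds (simulation, design,
turbulence) through ``numpy.random.SeedSequence([master, stage_index])``,
so each stage is individually reproducible and rerunning an identical
config reproduces identical artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .compress import measure, perturb_design
from .containers import ExpressionMatrix
from .design import generate_measurement_matrix, normalize_rows
from .evaluate import EvaluationReport, evaluate_reconstruction
from .reconstruct import (
    SolverConfig,
    block_reconstruct,
    make_reconstructor,
    partition_cells,
    threshold_expression,
)
from .simulate import SyntheticProfileSpec, simulate_scep

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "sweep", "stage_seed"]

# fixed stage indices of the seed-derivation scheme
_STAGE_SIM = 0
_STAGE_DESIGN = 1
_STAGE_TURBULENCE = 2


def stage_seed(master: int | None, stage: int) -> int:
    """Derive a per-stage 31-bit seed from the master seed."""
    base = 0 if master is None else int(master)
    state = np.random.SeedSequence([base, stage]).generate_state(1, dtype=np.uint32)
    return int(state[0] >> 1)


@dataclass
class PipelineConfig:
    """All parameters of one end-to-end run.

    Synthetic-data fields are ignored when ``expression_path`` points at
    a real expression matrix on disk.
    """

    # data source
    expression_path: str | None = None
    n_cells: int = 64
    n_genes: int = 2000
    target_nonzero_frac: float = 0.2449
    n_types: int = 7
    marker_frac: float = 0.3
    dispersion: float = 0.4
    mean_expression: float = 200.0
    # design
    n_pools: int = 35
    inclusion_prob: float = 0.5
    # compression
    turbulence: float = 0.0
    tpm_mode: bool = False
    # decoding
    method: str = "ridge"
    lambda_: float = 0.01
    bp_feasibility_tol: float = 1e-8
    nonneg: bool = False
    block_size: int | None = None
    n_workers: int = 1
    # thresholds
    floor_value: float = 0.0
    detect_tol: float = 0.001
    # misc
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        # delegate validation to the owning modules' parameter objects
        if self.expression_path is None:
            SyntheticProfileSpec(
                n_cells=self.n_cells,
                n_genes=self.n_genes,
                target_nonzero_frac=self.target_nonzero_frac,
                n_types=self.n_types,
                marker_frac=self.marker_frac,
                dispersion=self.dispersion,
                mean_expression=self.mean_expression,
                seed=0,
            )
        SolverConfig(
            method=self.method,
            lambda_=self.lambda_,
            bp_feasibility_tol=self.bp_feasibility_tol,
            nonneg=self.nonneg,
            n_workers=self.n_workers,
        )
        if self.n_pools < 1:
            raise ValueError("n_pools must be positive")
        if not 0 < self.inclusion_prob <= 1:
            raise ValueError("inclusion_prob must be in (0, 1]")
        if not 0 <= self.turbulence < 1:
            raise ValueError("turbulence must be in [0, 1)")
        if self.floor_value < 0 or self.detect_tol < 0:
            raise ValueError("floor_value and detect_tol must be nonnegative")
        if self.block_size is not None and self.block_size < 1:
            raise ValueError("block_size must be positive")

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            method=self.method,
            lambda_=self.lambda_,
            bp_feasibility_tol=self.bp_feasibility_tol,
            nonneg=self.nonneg,
            n_workers=self.n_workers,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_or_simulate(config: PipelineConfig) -> ExpressionMatrix:
    if config.expression_path is not None:
        return pio.read_expression(config.expression_path)
    spec = SyntheticProfileSpec(
        n_cells=config.n_cells,
        n_genes=config.n_genes,
        target_nonzero_frac=config.target_nonzero_frac,
        n_types=config.n_types,
        marker_frac=config.marker_frac,
        dispersion=config.dispersion,
        mean_expression=config.mean_expression,
        seed=stage_seed(config.seed, _STAGE_SIM),
    )
    return simulate_scep(spec)


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full chain; write artifacts when ``outdir`` is set."""
    logger.info("stage simulate/load")
    X = _load_or_simulate(config)
    if config.block_size is not None:
        logger.info("stage block-reconstruct (%d cells)", X.n_cells)
        partition = partition_cells(X.n_cells, config.block_size, config.n_pools)
        X_hat_raw = block_reconstruct(
            X,
            partition,
            config.solver_config(),
            seed=stage_seed(config.seed, _STAGE_DESIGN),
            inclusion_prob=config.inclusion_prob,
            turbulence=config.turbulence,
            tpm=config.tpm_mode,
            n_workers=config.n_workers,
        )
        design = None
        Y = None
    else:
        logger.info("stage design (%d pools x %d cells)", config.n_pools, X.n_cells)
        design = generate_measurement_matrix(
            config.n_pools,
            X.n_cells,
            config.inclusion_prob,
            seed=stage_seed(config.seed, _STAGE_DESIGN),
        )
        logger.info("stage compress (turbulence=%g)", config.turbulence)
        perturbed = perturb_design(
            design,
            config.turbulence,
            seed=stage_seed(config.seed, _STAGE_TURBULENCE),
        )
        if config.tpm_mode:
            row_sums = design.values.sum(axis=1)
            from .compress import PoolMatrix

            Y = PoolMatrix(
                values=(perturbed.values / row_sums[:, None]) @ X.values,
                normalized=True,
                gene_labels=list(X.gene_labels),
            )
            solver_design = normalize_rows(design)
        else:
            Y = measure(perturbed, X)
            solver_design = design.values
        logger.info("stage reconstruct (%s)", config.method)
        est = make_reconstructor(config.solver_config()).fit(solver_design)
        X_hat_raw = est.transform(Y)
    logger.info("stage threshold")
    X_hat, undetected = threshold_expression(
        X_hat_raw, detect_tol=config.detect_tol, floor_value=config.floor_value
    )
    logger.info("stage evaluate")
    report = evaluate_reconstruction(
        X, X_hat, n_pools=config.n_pools, detect_tol=config.detect_tol
    )
    if config.outdir is not None:
        _write_artifacts(config, X, design, Y, X_hat, report)
    return report


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(config, X, design, Y, X_hat, report) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_copy = dataclasses.replace(config, outdir=None)
    config_copy.to_yaml(outdir / "config.yaml")
    pio.write_expression(X, outdir / "expression.tsv")
    if design is not None:
        pio.write_design(design, outdir / "design.csv", cell_labels=X.cell_labels)
    if Y is not None:
        pio.write_pools(
            Y,
            outdir / "pools.tsv",
            turbulence=config.turbulence,
            seed=config.seed,
            design=design,
        )
    pio.write_expression(X_hat, outdir / "reconstructed.tsv")
    (outdir / "report.json").write_text(report.to_json() + "\n")
    pd.DataFrame(
        {"cell_id": report.cell_labels, "rho_c": report.per_cell_rho}
    ).to_csv(outdir / "per_cell_rho.tsv", sep="\t", index=False)
    report.gene_profile.to_csv(outdir / "per_gene_corr.tsv", sep="\t", index=False)
    pd.DataFrame(
        report.cell_by_cell_corr, index=report.cell_labels, columns=report.cell_labels
    ).to_csv(outdir / "cell_by_cell_corr.csv", index_label="cell_id")
    manifest = {
        "seed": config.seed,
        "files": {
            p.name: _file_hash(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def sweep(
    X,
    conditions: list[tuple[str, int, float]],
    n_repeats: int = 10,
    seed: int = 0,
    inclusion_prob: float = 0.5,
    lambda_: float = 0.01,
    bp_feasibility_tol: float = 1e-8,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Evaluate mean per-cell correlation over a grid of conditions.

    ``conditions`` is a list of ``(method, n_pools, turbulence)``
    triples.  For each repeat, the design and its perturbation depend
    only on ``(n_pools, turbulence, repeat)`` — not on the method — so
    the two decoders are compared on identical measurements (a paired
    design that removes design-draw variance from the comparison).

    Returns a long-format table with one row per (condition, repeat).
    """
    from .containers import as_expression_matrix
    from .evaluate import cell_correlations

    em = as_expression_matrix(X)
    # cache measurements per (n_pools, turbulence, repeat)
    rows = []
    cache: dict[tuple[int, float, int], tuple] = {}
    for method, n_pools, turbulence in conditions:
        for rep in range(n_repeats):
            key = (n_pools, turbulence, rep)
            if key not in cache:
                ss = np.random.SeedSequence(
                    [int(seed), n_pools, int(round(1000 * turbulence)), rep]
                )
                d_seed, t_seed = (
                    int(s >> 1) for s in ss.generate_state(2, dtype=np.uint32)
                )
                design = generate_measurement_matrix(
                    n_pools, em.n_cells, inclusion_prob, seed=d_seed
                )
                perturbed = perturb_design(design, turbulence, seed=t_seed)
                Y = measure(perturbed, em)
                cache[key] = (design, Y)
            design, Y = cache[key]
            solver = SolverConfig(
                method=method,
                lambda_=lambda_,
                bp_feasibility_tol=bp_feasibility_tol,
                n_workers=n_workers,
            )
            est = make_reconstructor(solver).fit(design.values)
            X_hat = est.transform(Y)
            _, mean_rho = cell_correlations(em, X_hat)
            rows.append(
                {
                    "method": method,
                    "n_pools": n_pools,
                    "turbulence": turbulence,
                    "repeat": rep,
                    "mean_rho": mean_rho,
                }
            )
            logger.debug(
                "sweep %s pools=%d t=%g rep=%d rho=%.4f",
                method,
                n_pools,
                turbulence,
                rep,
                mean_rho,
            )
    return pd.DataFrame(rows)
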