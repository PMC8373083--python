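# poolcs

Compressed-sensing inference of single-cell expression profiles from
overlapped pooled sequencing.

## The problem

Plate-based single-cell RNA-seq (Smart-Seq2-style) detects many genes
per cell and preserves each cell's identity, but builds one sequencing
library per cell — the dominant cost at scale. Single-cell expression
profiles (SCEPs) are sparse (typically only ~25–35% non-zero entries)
and correlated across cells, which makes them *compressible*: instead
of sequencing every cell, one can sequence a smaller number of
**overlapping pools** of cells and computationally recover each cell's
profile.

`poolcs` is for computational biologists and method developers who want
to design such pooling experiments, simulate them end to end, and decode
pooled measurements back into per-cell profiles.

## The model

Let `X ∈ R^{c×g}` be the (cells × genes) expression matrix and
`M ∈ {0,1}^{p×c}` a binary pool design with `m_ij = 1` iff pool *i*
contains an aliquot of cell *j*'s cDNA. Pooled sequencing measures

```
Y_{p×g} = M_{p×c} · X_{c×g},     p < c,
```

saving `c − p` libraries. Each gene column `x` is recovered from
`y = M x` by one of two decoders:

* **Basis pursuit** (ℓ1): `min ‖x‖₁ s.t. ‖Mx − y‖∞ ≤ ε`, a linear
  program; best for high-sparsity data with clean measurements.
* **Ridge regression** (ℓ2): the closed form
  `x̂ = (λI + MᵀM)⁻¹ Mᵀ y` with λ = 0.01; fast, and robust to noise
  and to low-sparsity data.

Multiplicative "turbulence" noise (each design 1 replaced by a uniform
draw from `(1−t, 1+t)` before measuring) models pipetting and
degradation error; a TPM mode (`Y = diag(1/rowsum(M)) M X`) models
pools whose member cells share sequencing depth; a block-parallel
scheme partitions large cell sets into independently designed and
decoded blocks. Recovery quality is scored by the per-cell Pearson
correlation `ρ_c` between original and recovered profiles and its mean
`ρ`, plus gene detection sensitivity and library-savings accounting.

See `docs/methods.md` for the full model description, the synthetic
data generator, and numerical choices.

## Worked example

```python
import poolcs as pc

# 64 cells x 2000 genes, ~24.5% non-zero, 7 cell types
X = pc.simulate_scep(pc.SyntheticProfileSpec(seed=1234))

# 35 pools instead of 64 libraries
design = pc.generate_measurement_matrix(n_pools=35, n_cells=64,
                                        inclusion_prob=0.5, seed=7)
Y = pc.measure(design, X)

# decode each gene by basis pursuit, then evaluate
X_hat = pc.basis_pursuit_solve(design, Y)
report = pc.evaluate_reconstruction(X, X_hat, n_pools=35)
print(f"mean rho = {report.mean_rho:.3f}")
saved, pct = report.savings
print(f"libraries saved: {saved} ({pct}%)")
```

prints

```
mean rho = 0.856
libraries saved: 29 (45.31%)
```

i.e. sequencing 35 pooled libraries instead of 64 per-cell libraries
(45% fewer) recovers per-cell profiles that correlate with the truth at
0.86 on average under these conditions. The same chain is available
from the shell:

```sh
poolcs simulate --cells 64 --genes 2000 --seed 1234 --out expr.tsv
poolcs design --pools 35 --cells 64 --prob 0.5 --seed 7 --out design.csv
poolcs compress --design design.csv --expr expr.tsv --out pools.tsv
poolcs reconstruct --design design.csv --pools pools.tsv --method bp --out recon.tsv
poolcs evaluate --truth expr.tsv --inferred recon.tsv --pools 35 --out eval/
```

plus `poolcs pipeline` (one YAML config for the whole chain) and
`poolcs sweep` (mean-ρ grids over pool counts and turbulence levels).

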