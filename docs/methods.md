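# Methods

## The measurement model

`poolcs` implements compressed sensing along the *cell* axis of a
single-cell expression profile (SCEP). Let `X ∈ R^{c×g}` be the
nonnegative, TPM-scale expression of `c` cells over `g` genes (cells as
rows — the transpose of the classic orientation, because each gene
column is an independent signal of length `c`). A binary design
`M ∈ {0,1}^{p×c}` with `m_ij = 1` iff pool `i` receives an aliquot of
cell `j`'s cDNA produces pooled measurements

```
Y = M X,          Y ∈ R^{p×g},   p < c.
```

Sequencing `p` pools instead of `c` cells saves `c − p` library
constructions (`library_savings`); recovery of `X̂` from `(M, Y)` is an
underdetermined linear inverse problem made tractable by the sparsity
of SCEPs (typically only ~25–35% of entries are non-zero).

### Designs

Designs are random Bernoulli matrices: each entry is 1 independently
with probability `inclusion_prob` (default 0.5; 0.3 is a sparser preset
that reduces bench work for very large cell numbers). Bernoulli
ensembles satisfy the restricted isometry property with high
probability once `p ≳ c_K · K · log(N/K)` for K-sparse signals of
length N; `required_pool_count` exposes this heuristic with the
constant and logarithm base as explicit parameters, because the theory
fixes only the scaling. It is advisory and never gates generation.

A draw containing an empty pool (wasted library) or an unpooled cell
(unrecoverable) is rejected and redrawn, up to `max_retries` (default
1000, each retry logged). Duplicate design columns make the
corresponding cells indistinguishable; this is warned about, not
rejected, since random designs may rarely collide.

### Noise: the turbulence model

Wet-lab error (pipetting variation, cDNA degradation, sequencing noise)
attaches to the cells actually present in a pool. With turbulence
`t ∈ [0,1)`, each design entry 1 is replaced by a uniform draw from the
open interval `(1−t, 1+t)`; zeros stay zero. Measurements use the
perturbed design; **decoding always uses the nominal binary design** —
this mismatch is precisely how noise degrades recovery. Draws landing
exactly on an interval endpoint are redrawn (a measure-zero event,
handled so the support contract is strict); a `t` small enough that
`1−t == 1` in floating point is a no-op.

### TPM mode

In the wet-lab path all cells of a pool share its sequencing depth, so
a TPM-normalized pool row is the *average* of its member cells:
`Y_tpm = diag(1/rowsum(M)) · M · X`. Decoding then uses the
row-normalized design `M_norm = diag(1/rowsum(M)) · M`. The identity
`measure_tpm(M, X) == measure(normalize_rows(M), X)` holds exactly
(same floating-point operations), and normalized rows sum to 1 within
1e-12.

## Decoders

Each gene column is decoded independently (embarrassingly parallel; the
contract requires order- and worker-count-independent results).

**Ridge regression (ℓ2).** Closed form `x̂ = (λI + MᵀM)⁻¹ Mᵀ y` with
λ = 0.01 by default (a documented grid-search optimum; λ trades
solution magnitude against data fit). The Cholesky factor of
`λI + MᵀM` is computed once per design and reused across all genes, so
decoding 2000 genes costs one factorization plus 2000 triangular
solves. Ridge smooths sparse signals but is robust to measurement
noise.

**Basis pursuit (ℓ1).** Per gene, `min ‖x‖₁ s.t. ‖Mx − y‖∞ ≤ ε`,
solved as the standard split-variable LP (`x = x⁺ − x⁻`, `x± ≥ 0`) with
HiGHS. Equality constraints (`Mx = y`) are brittle with floating-point
TPM values, so feasibility is an infinity-norm tube of width
`ε = tol · ‖y‖∞` with `tol = 1e-8` — equality in exact arithmetic. A
zero measurement column short-circuits to `x̂ = 0` (feasible with
minimal norm). Infeasible LPs are reported with their gene labels,
distinctly from non-convergence. HiGHS presolve is disabled: on these
small dense LPs it costs more than it saves (~30% measured). An
optional `nonneg` flag drops `x⁻`.

Neither decoder clamps negative outputs; nonnegativity, the TPM
detection floor (values < 0.001 treated as unexpressed) and the
accuracy floor (values < 5 zeroed, when enabled) are applied downstream
by `threshold_expression`, so raw solver output stays comparable to
analytic oracles.

### Choosing a decoder

On high-sparsity data with clean measurements, basis pursuit dominates:
its ℓ1 prior matches the signal and recovery of sparse genes is
near-exact. As turbulence grows, the tube constraint forces BP to fit
noise exactly while ridge distributes the error; at `t = 0.6` ridge's
mean per-cell correlation exceeds BP's. On low-sparsity data ridge is
preferable throughout, and it is orders of magnitude faster.

## Block-parallel decoding

For large `c`, cells are partitioned into contiguous blocks
(`partition_cells`), each with its own independently generated design,
and decoded separately (`block_reconstruct`); recovered blocks are
concatenated in the original cell order. All blocks hold `block_size`
cells except the last: a cell remainder smaller than half a block is
merged into the final block (5063 cells at size 500 → 9×500 + 563),
while a larger remainder keeps its own smaller block (45423 cells →
90×500 + 423). Pools are apportioned proportionally to block size,
`round(block_size · total_pools / n_cells)` per regular block, with the
remainder of pools assigned to the last block (1600 pools over the
5063-cell layout → 9×158 + 178; 22700 over the 45423-cell layout →
90×250 + 200).

Per-block seeds derive deterministically from
`SeedSequence([master_seed, block_index])`, so results are bitwise
identical whether blocks run serially or in parallel, and a one-block
partition reproduces the unblocked pipeline exactly.

## Evaluation metrics

* **Per-cell Pearson correlation** `ρ_c` between each original and
  recovered cell row; the mean `ρ` over cells is the headline
  consistency metric. Cells with zero variance in either matrix have
  undefined correlation; they are excluded from the mean with a logged
  warning rather than coerced to 0, which would bias `ρ` downward.
* **Cell-by-cell correlation matrix** (original × inferred), the
  heat-map source; its diagonal equals `ρ_c`.
* **Detection sensitivity**: a gene counts as detected when its total
  over cells is ≥ 0.001 (the TPM floor); reported as counts for both
  matrices, their ratio, and the number of lost genes whose original
  total exceeds a high-expression threshold (default TPM 1).
* **Gene correlation profile**: per-gene correlation across cells,
  binned into quantile groups (default quintiles — the bin count is a
  package choice; rank strata are conventional for these violin-style
  summaries) ranked either by sparsity level (expressing-cell count
  ascending: sparsest first) or by total expression. Sparse genes are
  recovered best by ℓ1 decoding; dense gene recovery is the known weak
  point of both decoders.
* **Library savings**: `max(c − p, 0)` and the percentage of `c`,
  rounded to two decimals (54 cells in 28 pools → 26 libraries, 48.15%).

## The synthetic SCEP generator

`simulate_scep` emulates plate-based SCEPs parametrically so the whole
pipeline is testable at any scale without external data. Two reference
regimes guide the defaults: a "high sparsity" regime (~24.49% non-zero,
seven heterogeneous cell types, low between-cell correlation) and a
"low sparsity" regime (~32.30% non-zero, six closely related types).

Mechanics (all draws from one seeded generator):

1. Cells are assigned to `n_types` balanced types; `marker_frac`
   (default 0.3) of genes are type-specific markers with baseline
   expression probability 0.85 in their own type and 0.05 elsewhere.
2. Non-marker genes split into a housekeeping stratum (40%, expression
   probability uniform on 0.7–0.98) and a rare tail
   (Beta(0.45, 2.2)) — the bimodal sparsity-level profile of real
   plate-based data, and the source of the baseline correlation
   unrelated cells exhibit.
3. All probabilities are rescaled by one multiplier, found by bisection
   with clipping at 1, so the expected non-zero fraction equals
   `target_nonzero_frac` exactly; the zero mask is then Bernoulli. The
   realized fraction concentrates within well under ±2 percentage
   points of the target at the 64×2000 scale.
4. Expressed magnitudes are gamma draws (shape `dispersion`, default
   1.5 — a negative-binomial-like heavy tail) around a per-gene mean
   `mean_expression · density · LogNormal(σ=1.8)`, with marker genes
   upregulated 4-fold in their own type. The proportionality of mean
   magnitude to expression probability implements the dropout–mean
   relationship of scRNA-seq: the highest-expression genes are the
   dense, housekeeping-like ones. Without this coupling the largest
   genes land anywhere in the sparsity spectrum, which makes synthetic
   data unrealistically favorable to ℓ1 decoding under noise.

What the generator does *not* model: read-level sampling, UMIs, batch
effects, per-cell library-size variation (irrelevant to Pearson
metrics, which are scale-invariant per cell), and exact dataset
medians of cell–cell correlation — the defaults land near 0.25–0.3
where the high-sparsity reference sits at 0.147; the generator exposes
type count, marker fraction and dispersion rather than targeting that
statistic directly. Passing tests on synthetic data therefore
demonstrate the pipeline's mathematical behavior (trends, crossovers,
identities, determinism), not real-data performance levels.

## Study sizes and numerical choices

The documented trend study uses a 64-cell × 2000-gene high-sparsity
profile, pool counts {15, 20, 25, 30, 35, 40, 45}, turbulence
{0, 0.2, 0.4, 0.6}, and 10 seeded repeats per condition. Ridge is
evaluated on the full grid; basis pursuit on the margins the
conclusions read (the pool sweep at t = 0 and the turbulence sweep at
35 pools), since one BP run solves 2000 LPs and the full grid would
quadruple runtime without adding information. Designs and perturbations
are seeded by (pool count, turbulence, repeat) only, so the two
decoders see identical measurements — a paired comparison that removes
design-draw variance from the BP-vs-ridge contrast.

The uncompressed control (p = c = 64) uses the best-conditioned of 200
seeded square Bernoulli draws: a random square 0/1 matrix is invertible
essentially always but can have condition number in the thousands, and
a near-singular draw would measure conditioning rather than decoding.

Other numerical choices: ridge guards its Cholesky factorization with a
pseudoinverse fallback (unreachable for λ > 0); per-stage seeds derive
from one master seed via `SeedSequence([master, stage])`, keeping every
stage individually reproducible; artifacts are written with `%.17g`
float formatting and re-read with round-trip parsing, so file
round-trips are bit-exact and pipeline reruns hash-identical.

## Limitations

* Recovery of densely expressed genes is mediocre for both decoders —
  an intrinsic limit of unregularized-prior compressed sensing on
  non-sparse components, visible in the gene correlation profile.
* The turbulence model is multiplicative and design-borne only; no
  additive background, depth variation, or count noise.
* λ = 0.01 is the only documented ridge setting; `sweep` supports
  user-supplied grids but no other default is claimed.
* Low-rank or dictionary priors exploiting cell–cell similarity (which
  would help dense genes) are out of scope.
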