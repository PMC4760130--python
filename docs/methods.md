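# Methods

## Model

Module activity scoring rests on the one-factor linear model of gene
regulation: for the genes of a module, expression is approximated as
`X[g, s] ≈ α_g A_s + B_s` with unit-norm response coefficients `α` and a
per-sample hidden-factor activity `A`.  Fitting this model in least squares
is equivalent to extracting the first principal component of the
module-restricted matrix; `L1`, the fraction of (weighted) variance
explained by that component, is the module's overdispersion score, and
`L1/L2` — the gap to the second component — its coordination score.

The package assumes row-centered, roughly log-scale expression.  Row
centering (`Σ_s X[g, s] = 0` per gene) is applied by default because
otherwise PC1 tends to capture differences in basal expression level rather
than variation across samples.  Double-centering additionally removes
per-sample offsets, but since different gene sets sit at different offsets
from the global center it cannot hold for all modules simultaneously; it is
therefore an option, not the default.

### Fitting algorithm

The component is computed by alternating least squares (the iterative SVD
power method): starting from a random activity vector,

```
α_g ← Σ_s X'[g,s] A_s / Σ_s A_s²
α   ← normalise(α − weighted_mean(α))        (standard mode only)
A_s ← Σ_g |w_g| α_g X'[g,s] / Σ_g |w_g| α_g²
```

until the relative change of `α` (after sign alignment) falls below `tol`
(default 1e-9; `max_iter` 10 000; the starting vector is drawn from a seeded
RNG, default seed 0, so runs are bit-reproducible).  `X'` is the submatrix
minus its intercept:

* **standard mode** — the intercept is the per-sample weighted mean over
  module genes, and the weighted mean of `α` is subtracted each sweep.  This
  projection enforces the zero-sum loading constraint of the centered model;
  with unit weights it is exactly the plain-mean subtraction of the textbook
  constraint, and with non-unit weights the weighted form is used because it
  is the projection that leaves the weighted-SVD fixed point invariant (the
  dense-eigensolver cross-checks in the test suite hold at 1e-8 only with
  this form).
* **fixed-center mode** (default) — the intercept is the global center
  `C_s`, the mean over *all* dataset genes of the preprocessed matrix, and
  no zero-sum constraint is imposed (all loadings may share a sign, as for a
  uniformly activated target set).

Weights affect the objective and the activity update but `α` is normalised
in the unweighted Euclidean norm, following the printed form of the
constraint; rescaling all weights by a constant leaves the fit unchanged.

`L1 = 1 − ‖X' − αAᵀ‖²_w / ‖X'‖²_w` with `‖M‖²_w = Σ_g |w_g| Σ_s M[g,s]²`.
The second component is obtained by running the same iteration on the
deflated residual `X' − αAᵀ`, and `L2` is its share of the *original* total;
this matches the spectrum of the weighted covariance exactly and is how the
engine is cross-checked against `numpy.linalg.eigvalsh`.  A submatrix whose
centered weighted norm is zero raises a degenerate-module error; an exactly
rank-1 submatrix gets `L2 = 0` and an infinite coordination ratio.

At convergence the per-gene projection on component 2 is reported as
`X' · v₂` with `v₂` the unit activity direction of the second component.

### Orientation

PC1 is defined up to sign.  If the module description marks some genes as
activators/inhibitors (signed weights), the orientation with
`Σ_{g∈W} w_g α_g > 0` is chosen, where `W` is the signed subset.  Without
usable signs (or at an exact zero sum) the activity is aligned to correlate
non-negatively with the module's mean expression profile; an exactly zero
correlation leaves the fit as computed and logs the fact.  Orientation is
idempotent and never touches component 2.

### Robust filtering

A single aberrant gene can dominate PC1.  Before the final fit, each gene is
left out in turn and `L1` recomputed; the leave-one-out values are converted
to z-scores (sample standard deviation, n−1), and genes with `|z| > z_max`
(default 3.0) are removed in one single pass — the filter is not iterated,
and leave-one-out "points" are genes (rows), not samples.  With fewer than
three genes the distribution is degenerate and filtering is skipped with a
warning; a zero standard deviation removes nothing.  Note that with n genes
the largest attainable |z| is (n−1)/√n, so z_max = 3 can only ever remove
anything for modules of 11+ genes — intended, since leave-one-out outlier
calls on smaller sets would be noise.

## Significance

Any random gene set lets PC1 explain some variance, and both `L1` and
`L1/L2` depend strongly on set size.  Each module is therefore compared to
`K` uniformly drawn gene sets of the same size (unit weights, no robust
filtering — a random set has no prior structure to weight or defend),
fitted in the same mode and against the same global center as real modules.
The empirical p-value uses the add-one convention
`p = (1 + #{null ≥ observed}) / (K + 1)`, so p = 0 is impossible and the
default `K = 999` gives a floor of 0.001.

Building a null per distinct module size would be wasteful, so nulls are
computed on a grid of sizes spaced uniformly in log scale between the
smallest and largest *retained* (post-matching, post-outlier) module size
(`n_grid` default 10, endpoints always included), and each module uses the
grid size nearest in log scale (ties toward the smaller size).  Per-size RNG
streams are derived from `(seed, size)`, so enlarging the grid never changes
existing nulls.  Raw p-values are reported; Benjamini–Hochberg adjusted
columns are emitted additionally and clearly labelled.

## Workflow

`ROMA.fit()` runs: impute (if `impute_k_rank` is set) → center per config →
global center → per module: exact gene matching (case folding is opt-in,
since silent folding corrupts protein identifiers), skip with a logged
reason when fewer than `min_module_size` (default 8) genes match → robust
filter → weighted PC1 on retained genes → orientation → nulls via the size
grid → p-values → score table, activity matrix and per-gene projection
tables.  Outputs are byte-identical across runs with the same config and
seeds.  The two-group comparison applies a per-module two-sided two-sample
Kolmogorov–Smirnov test (asymptotic p) to activity scores split by an
annotation column.

## Missing values

Missing entries are imputed before any module extraction by approximating
the matrix with a complete lower-rank one: a per-sample intercept plus
`k_rank` multiplicative components, fitted to the observed cells only by
alternating least squares (each gene row and sample column has a
closed-form update; the same update structure as the PC1 iteration, with
sums restricted to observed entries).  The fit is warm-started from a
truncated SVD of the mean-filled matrix, iterated to a relative
reconstruction change below 1e-8 (default, max 1000 sweeps), and only the
missing cells are replaced — observed values are preserved exactly.  The
user chooses `k_rank`; a fully missing row or column is an error.  The
global center is computed after imputation.

## Synthetic data

The generator produces exactly what the scorer inverts: planted genes
follow `X[g,s] = Σ_k α_k[g] A_k[s] + ε`, `ε ~ N(0, σ²)`, embedded in iid
Gaussian background genes, with rows subsequently centered.  Signal-to-noise
is quoted per gene: `|α_g|·sd(A) / σ`.  One factor gives a coordinated,
overdispersed module; two or more independent factors (genes split into
blocks, one factor each) give an overdispersed but uncoordinated one.  Half
of each planted module's genes carry signed GMT weights matching their
loading signs, exercising orientation end to end.  The generator makes no
attempt at realistic count distributions (dropout, library size,
mean–variance coupling), so passing tests demonstrate correctness of the
inference machinery on its own model class, not robustness to single-cell
technical noise.

Default study conditions used by the recovery and calibration checks:
planted modules of 50 genes × 20 samples at per-gene SNR 2 among 500
background genes (20 replicates, K = 199); null calibration on a 2000-gene
× 30-sample iid Gaussian matrix with 200 test modules of sizes
8/16/32/64/128 and K = 200 per size.  These sizes keep the whole suite and
the acceptance script within about a minute while leaving the statistics
comfortably clear of their thresholds.

## Numerical notes and limitations

* Convergence of the power iteration slows as the spectral gap closes; the
  explained-variance fractions are second-order insensitive to the iterate
  within a near-degenerate leading subspace, so `L1`/`L2` remain accurate
  even when the loading direction itself has not settled (a warning is
  logged after `max_iter`).
* The module score table renders floats with 8 significant digits;
  round-tripping through the written files preserves at least 6.
* p-values are discrete with resolution `1/(K+1)`; K should be raised for
  fine FDR work.
* Components beyond the second, analytic null approximations
  (Tracy–Widom), and per-gene permutation nulls are out of scope.
* The GMT weight dialect (`GENE[w]` bracket suffix) is a convention of this
  package; plain GMT files parse unchanged with unit unsigned weights.
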