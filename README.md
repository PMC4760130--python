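# roma-activity

Quantification of gene-module activity in individual samples from bulk or
single-cell expression data, via the first principal component of the
module-restricted expression matrix.

## The problem

Many analyses need a per-sample activity estimate for a *module* — a set of
functionally related genes such as the targets of a transcription factor, a
signalling pathway, or a co-expression cluster — when the driving factor
itself (the TF protein, the kinase) is not directly measurable.  Averaging
the member genes fails whenever genes contribute unequally or with opposite
signs (activated vs repressed targets).

This package models a module's expression with the simplest one-factor
linear model

```
Expression(g, s) ≈ α_g · Activity_s + B_s ,        Σ_g α_g² = 1
```

where `α_g` is gene *g*'s response coefficient to the hidden factor,
`Activity_s` its activity in sample *s*, and `B_s` a per-sample offset.  The
least-squares solution is the first principal component (PC1) of the
module-restricted matrix, computed here by the classical iterative
(alternating) SVD algorithm.  On top of the plain fit the package provides:

* **weighted PC1** — per-gene weight magnitudes `|w_g|` from the module
  definition enter the objective, so trusted genes pull the component harder;
* **fixed-center PC1** (the default) — the component is constrained to pass
  through the center of the *global* data distribution instead of the
  module's own centroid, so gene sets that are *shifted* with respect to the
  bulk are captured alongside overdispersed ones;
* **orientation** — the PC1 sign ambiguity is resolved so that
  `Σ_{g signed} w_g α_g > 0` using genes with a priori activator/inhibitor
  signs (falling back to positive correlation with the module's mean
  profile);
* **robust fitting** — a leave-one-out pass removes genes whose presence
  changes the explained variance aberrantly (`|z| > z_max`, default 3.0);
* **empirical significance** — a module's overdispersion `L1` (variance
  fraction explained by PC1) and coordination `L1/L2` (spectral gap) are
  compared against K random gene sets of the same size, with null
  distributions shared across modules on a log-scale size grid; p-values use
  the add-one convention, so the attainable minimum is `1/(K+1)`.

A module with significant `L1` is *overdispersed*; one with significant
`L1/L2` is *coordinated* (a single dominant factor).  Two independent
factors acting on one set give high `L1` with an unremarkable `L1/L2`.

## Worked example

Generate a synthetic dataset with one planted 30-gene single-factor module
(per-gene signal-to-noise 2) among 500 background genes, plus one random
control set, and score both:

```python
import numpy as np
from roma import ROMA, generate, single_factor_spec

spec = single_factor_spec("CELL_CYCLE", n_genes=30, n_samples=20, snr=2.0, rng=42)
X, truth, modules = generate(
    n_background_genes=500, n_samples=20, specs=[spec],
    seed=42, n_control_modules=1, control_size=30,
)
results = ROMA(X, modules, null_K=199).fit()
print(results.summary())

act = results.activity.loc["CELL_CYCLE"].to_numpy()
r = np.corrcoef(act, truth["CELL_CYCLE"]["activities"][0])[0, 1]
print(f"correlation with the planted factor activity: {r:.3f}")
```

prints

```
Module activity summary
======================================================================
dataset: 530 genes x 20 samples
mode: fixed_center PC1, centering=rows, robust z_max=3.0
null: K=199 random sets per size, grid sizes [30]
modules: 2 scored, 0 skipped
----------------------------------------------------------------------
     module  size_in_file  size_effective     L1  p_L1  L1_div_L2  p_L1_div_L2  n_outliers  q_L1_BH  q_L1_div_L2_BH
 CELL_CYCLE            30              30 0.7523 0.005      19.41        0.005           0     0.01            0.01
CONTROL_001            30              30 0.1353 0.975      1.054        0.975           0    0.975           0.975

correlation with the planted factor activity: 0.993
```

The planted module explains 75% of its submatrix variance (`L1 = 0.75`) with
a strong spectral gap (`L1/L2 = 19.4`) — overdispersed *and* coordinated at
the minimum attainable p-value `1/(K+1) = 0.005` — while the random control
set sits squarely in the null.  The recovered per-sample activity tracks the
planted factor at r = 0.99.

The same workflow is available from the shell:

```
roma simulate --genes 500 --samples 20 --seed 42 --out sim --controls 1
roma run --data sim/expression.tsv --gmt sim/modules.gmt --out results --nulls 199
roma compare --activities results/activities.tsv --samples ann.tsv \
     --feature group --a invasive --b superficial
```

`roma run` writes the module score table, the module × sample activity
matrix and one per-gene projection table per module; `roma compare` performs
a per-module two-sample Kolmogorov–Smirnov test of the activity scores
between two annotated sample groups.

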