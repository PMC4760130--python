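"""Empirical significance of module overdispersion and coordination.

PC1 explains some variance for *any* gene set, so a module's scores are only
meaningful against what random gene sets of the same size achieve on the same
data.  For a gene-set size ``n`` the null distribution is built by drawing
``K`` random ``n``-gene subsets of the dataset and recording their ``L1``
(overdispersion) and ``L1/L2`` (coordination) under the same fitting mode as
real modules.  Both statistics depend strongly on set size, so nulls are
computed on a grid of sizes spaced uniformly in log scale between the
smallest and largest module, and each module is compared against the grid
size nearest in log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import ExpressionMatrix
from .exceptions import RomaError
from .pca import DEFAULT_MAX_ITER, DEFAULT_TOL, Mode, fit_pc1


@dataclass
class NullDistribution:
    """L1 and L1/L2 values of K random gene sets of one fixed size."""

    size: int
    l1_samples: np.ndarray
    ratio_samples: np.ndarray

    def __post_init__(self) -> None:
        self.l1_samples = np.asarray(self.l1_samples, dtype=float)
        self.ratio_samples = np.asarray(self.ratio_samples, dtype=float)
        if self.l1_samples.size == 0 or self.l1_samples.size != self.ratio_samples.size:
            raise ValueError("null distribution needs K >= 1 paired samples")

    @property
    def K(self) -> int:
        return int(self.l1_samples.size)


@dataclass
class ModuleScore:
    """Final per-module record written to the module score table."""

    module: str
    size_in_file: int
    size_effective: int
    L1: float
    p_L1: float
    ratio: float
    p_ratio: float
    activity: np.ndarray
    outliers: list[str] = field(default_factory=list)
    null_size: int | None = None      #: grid size that served both p-values
    q_L1: float = float("nan")        #: Benjamini-Hochberg adjusted p_L1
    q_ratio: float = float("nan")     #: Benjamini-Hochberg adjusted p_ratio


def build_size_grid(min_size: int, max_size: int, n_grid: int) -> list[int]:
    """Gene-set sizes spaced uniformly in log scale, ends included.

    Rounded to integers, clamped to ``[min_size, max_size]``, deduplicated
    and sorted.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if min_size > max_size:
        raise RomaError(f"min_size {min_size} exceeds max_size {max_size}")
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    if min_size == max_size:
        return [min_size]
    pts = np.exp(np.linspace(np.log(min_size), np.log(max_size), n_grid))
    sizes = np.clip(np.rint(pts).astype(int), min_size, max_size)
    return sorted(set(sizes.tolist()) | {min_size, max_size})


def sample_null(
    X: ExpressionMatrix,
    size: int,
    K: int,
    mode: Mode = "standard",
    center: np.ndarray | None = None,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> NullDistribution:
    """Null L1 and L1/L2 from K uniformly drawn gene subsets of ``size``.

    Null sets are fitted with unit weights and no robust filtering (a random
    set carries no prior structure to weight or to defend against).  The RNG
    stream is derived from ``(seed, size)``, so adding grid sizes later never
    changes already-computed nulls.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if size > X.n_genes:
        raise RomaError(f"null set size {size} exceeds the {X.n_genes} dataset genes")
    if size < 2:
        raise ValueError("null set size must be >= 2")
    if X.has_missing:
        raise RomaError("null sampling requires a complete (imputed) matrix")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(size,)))
    n_genes = X.n_genes
    l1 = np.empty(K)
    ratio = np.empty(K)
    for k in range(K):
        rows = rng.choice(n_genes, size=size, replace=False)
        fit = fit_pc1(
            X.values[rows],
            weights=None,
            mode=mode,
            center=center,
            seed=int(rng.integers(2**31)),
            tol=tol,
            max_iter=max_iter,
        )
        l1[k] = fit.L1
        ratio[k] = fit.ratio
    return NullDistribution(size=size, l1_samples=l1, ratio_samples=ratio)


def empirical_pvalue(observed: float, null_samples: np.ndarray) -> float:
    """Add-one empirical p-value: ``(1 + #{null >= observed}) / (K + 1)``.

    The add-one convention makes p = 0 impossible; the attainable minimum is
    ``1 / (K + 1)``.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise RomaError("empirical p-value needs at least one null sample")
    if not np.isfinite(observed) and observed < 0:
        raise ValueError("observed statistic must not be -inf")
    count = int(np.sum(null_samples >= observed))
    return (1 + count) / (null_samples.size + 1)


def nearest_null(
    size: int, grids: Mapping[int, NullDistribution]
) -> NullDistribution:
    """Grid null whose size is closest to ``size`` in log scale.

    Ties break toward the smaller grid size.
    """
    if not grids:
        raise RomaError("no null distributions available")
    best: NullDistribution | None = None
    best_dist = np.inf
    for gsize in sorted(grids):
        d = abs(np.log(size) - np.log(gsize))
        if d < best_dist - 1e-12:
            best_dist = d
            best = grids[gsize]
    assert best is not None
    return best


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from scipy.stats import false_discovery_control

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return false_discovery_control(p, method="bh")
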