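"""Rank-1/rank-2 fits of module-restricted expression by iterative SVD.

A module's activity model is ``X[g, s] ~ alpha[g] * Activity[s] + B[s]``:
every gene in the set responds (with gene-specific coefficient ``alpha``) to
one hidden factor whose activity varies over samples.  The best-fit ``alpha``
and ``Activity`` are the first singular pair of the (weighted, centered)
submatrix, found here by the classical alternating power iteration: from a
random activity vector, alternately regress genes on the activity and the
activity on the genes until the loading vector stabilises.

Three variants are provided:

* standard — the per-sample intercept ``B`` is the (weight-)mean over module
  genes, i.e. PCA of the module's own point cloud;
* weighted — gene weights ``|w_g|`` enter the least-squares objective, so
  trusted genes pull the component harder;
* fixed center — the component is forced through the global data-distribution
  center instead of the module centroid, which also captures modules that are
  *shifted* with respect to the bulk rather than overdispersed.

``L1`` and ``L2`` are the fractions of (weighted) variance explained by the
first and second components; the second component comes from refitting the
deflated residual.  A leave-one-out filter removes genes whose presence
aberrantly changes ``L1`` before the final fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .containers import ModuleDefinition
from .exceptions import DegenerateModuleError, RomaError

logger = logging.getLogger(__name__)

Mode = Literal["standard", "fixed_center"]

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 10_000
DEFAULT_Z_MAX = 3.0


@dataclass
class PC1Fit:
    """Result of a rank-1 (+ deflated rank-2) fit of a module submatrix."""

    loadings: np.ndarray          #: unit-norm gene coefficients alpha_g
    activity: np.ndarray          #: per-sample factor activity Activity_s
    intercept: np.ndarray         #: per-sample B_s (standard) or the fixed center C_s
    L1: float                     #: variance fraction explained by component 1
    L2: float                     #: variance fraction explained by component 2
    pc2_proj: np.ndarray          #: per-gene projection on the second component
    mode: Mode
    n_iter: int
    converged: bool = True
    gene_names: list[str] | None = None
    module_mean: np.ndarray | None = None   #: per-sample unweighted mean of the submatrix

    @property
    def ratio(self) -> float:
        """Coordination score L1/L2 (inf for an exactly rank-1 submatrix)."""
        if self.L2 == 0.0:
            return float("inf")
        return self.L1 / self.L2


@dataclass
class OutlierReport:
    """Leave-one-out robustness diagnostics for one module."""

    removed_genes: list[str] = field(default_factory=list)
    loo_L1: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_max: float = DEFAULT_Z_MAX


def _als_component(
    X: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    zero_mean_alpha: bool,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """One power-iteration component of the weighted rank-1 problem.

    Minimises ``sum_g w_g sum_s (X[g,s] - alpha[g] A[s])**2`` by alternating
    the closed-form updates for ``alpha`` and ``A``.  ``alpha`` is normalised
    to unit Euclidean norm each sweep; with ``zero_mean_alpha`` its
    (weight-)mean is removed first, which projects the iterate back onto the
    subspace the intercept subtraction already spans and enforces the
    zero-sum loading constraint of the centered model.
    """
    n_genes, n_samples = X.shape
    A = rng.standard_normal(n_samples)
    alpha_prev: np.ndarray | None = None
    n_iter = 0
    converged = False
    w_sum = w.sum()
    for n_iter in range(1, max_iter + 1):
        denom = A @ A
        if denom == 0.0:
            A = rng.standard_normal(n_samples)
            continue
        alpha = X @ A / denom
        if zero_mean_alpha:
            alpha = alpha - (w @ alpha) / w_sum
        norm = np.linalg.norm(alpha)
        if norm == 0.0:
            # X annihilates A: restart from a fresh direction
            A = rng.standard_normal(n_samples)
            alpha_prev = None
            continue
        alpha /= norm
        A = (w * alpha) @ X / (w @ alpha**2)
        if alpha_prev is not None:
            if alpha @ alpha_prev < 0:
                alpha_cmp = -alpha
            else:
                alpha_cmp = alpha
            if np.linalg.norm(alpha_cmp - alpha_prev) < tol:
                alpha = alpha_cmp
                A = (w * alpha) @ X / (w @ alpha**2)
                converged = True
                break
        alpha_prev = alpha
    return alpha, A, n_iter, converged


def _weighted_sq_norm(M: np.ndarray, w: np.ndarray) -> float:
    return float(w @ (M**2).sum(axis=1))


def fit_pc1(
    X_mod: np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
    mode: Mode = "standard",
    center: np.ndarray | None = None,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    gene_names: Sequence[str] | None = None,
) -> PC1Fit:
    """Fit the rank-1 activity model to a complete module submatrix.

    Parameters
    ----------
    X_mod
        Complete (no missing values) genes x samples submatrix, already
        preprocessed (row-centered or as configured).
    weights
        Per-gene weight magnitudes ``|w_g|`` (signs are handled at
        orientation time); default all ones.
    mode
        ``"standard"`` subtracts the weighted per-sample gene mean as
        intercept; ``"fixed_center"`` subtracts the supplied global
        ``center`` and drops the zero-sum loading constraint.
    center
        Global per-sample center ``C_s``; required in fixed-center mode.
    seed
        Seeds the random start of the power iteration (bit-reproducible).

    Raises
    ------
    DegenerateModuleError
        If the centered submatrix has zero weighted variance.
    """
    X = np.asarray(X_mod, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise RomaError(f"need at least 2 genes and 2 samples, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise RomaError("module submatrix contains non-finite entries")
    n_genes, n_samples = X.shape
    if weights is None:
        w = np.ones(n_genes)
    else:
        w = np.abs(np.asarray(weights, dtype=float))
        if w.shape != (n_genes,):
            raise ValueError("weights length must equal the number of genes")
        if np.any(w == 0):
            raise ValueError("weights must be non-zero")

    if mode == "standard":
        intercept = (w @ X) / w.sum()
    elif mode == "fixed_center":
        if center is None:
            raise RomaError("fixed_center mode requires the global center vector")
        intercept = np.asarray(center, dtype=float)
        if intercept.shape != (n_samples,):
            raise ValueError("center length must equal the number of samples")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    Xc = X - intercept[None, :]
    total = _weighted_sq_norm(Xc, w)
    if total <= 1e-300:
        raise DegenerateModuleError("module submatrix has zero variance about its center")

    rng = np.random.default_rng(seed)
    zero_mean = mode == "standard"
    alpha, A, it1, conv1 = _als_component(Xc, w, rng, tol, max_iter, zero_mean)
    resid1 = Xc - np.outer(alpha, A)
    L1 = 1.0 - _weighted_sq_norm(resid1, w) / total

    # second component from the deflated residual, same iteration
    resid_norm = _weighted_sq_norm(resid1, w)
    if resid_norm <= 1e-12 * total:
        L2 = 0.0
        pc2_proj = np.zeros(n_genes)
        it2, conv2 = 0, True
    else:
        alpha2, A2, it2, conv2 = _als_component(resid1, w, rng, tol, max_iter, zero_mean)
        resid2 = resid1 - np.outer(alpha2, A2)
        L2 = (resid_norm - _weighted_sq_norm(resid2, w)) / total
        a2n = np.linalg.norm(A2)
        pc2_proj = Xc @ (A2 / a2n) if a2n > 0 else np.zeros(n_genes)

    if not (conv1 and conv2):
        logger.warning(
            "PC iteration did not converge within %d iterations (module of %d genes); "
            "returning the current iterate", max_iter, n_genes,
        )
    return PC1Fit(
        loadings=alpha,
        activity=A,
        intercept=intercept,
        L1=float(L1),
        L2=float(max(L2, 0.0)),
        pc2_proj=pc2_proj,
        mode=mode,
        n_iter=it1 + it2,
        converged=conv1 and conv2,
        gene_names=list(gene_names) if gene_names is not None else None,
        module_mean=X.mean(axis=0),
    )


def orient_pc1(fit: PC1Fit, module: ModuleDefinition) -> PC1Fit:
    """Resolve the PC1 sign ambiguity from prior activator/inhibitor signs.

    If the signed-weight genes' contribution ``sum_{g signed} w_g alpha_g``
    is negative, component 1 (loadings and activity) is negated.  When the
    module carries no usable signed genes (or the sum is exactly zero), the
    component is oriented so that the activity correlates non-negatively with
    the per-sample mean expression of the module; a zero correlation leaves
    the fit untouched and logs the fact.  The second component is never
    changed.
    """
    if fit.gene_names is None:
        raise RomaError("orientation needs gene_names on the fit")
    by_name = {g.name: g for g in module.genes}
    signed_sum = 0.0
    any_signed = False
    for name, a in zip(fit.gene_names, fit.loadings):
        gene = by_name.get(name)
        if gene is not None and gene.sign_defined:
            signed_sum += gene.weight * a
            any_signed = True

    if any_signed and signed_sum != 0.0:
        if signed_sum < 0:
            return _negate_component1(fit)
        return fit

    # fallback: align activity with the module's mean expression profile
    if fit.module_mean is None:
        raise RomaError("orientation fallback needs module_mean on the fit")
    mean_prof = fit.module_mean - fit.module_mean.mean()
    act = fit.activity - fit.activity.mean()
    corr = float(act @ mean_prof)
    if corr < 0:
        return _negate_component1(fit)
    if corr == 0:
        logger.info("module %s: orientation undetermined; leaving PC1 as computed", module.name)
    return fit


def _negate_component1(fit: PC1Fit) -> PC1Fit:
    return replace(fit, loadings=-fit.loadings, activity=-fit.activity)


def robust_filter(
    X_mod: np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
    mode: Mode = "standard",
    center: np.ndarray | None = None,
    z_max: float = DEFAULT_Z_MAX,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    gene_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, OutlierReport]:
    """Leave-one-out outlier removal on the explained-variance fraction.

    For every gene ``i`` the model is refitted with that gene's row removed
    and the resulting ``L1`` recorded.  The distribution of these
    leave-one-out values is converted to z-scores (sample standard
    deviation); genes with ``|z| > z_max`` are removed in a single pass.
    Returns the indices of retained genes and a diagnostic report.
    """
    X = np.asarray(X_mod, dtype=float)
    n_genes = X.shape[0]
    names = list(gene_names) if gene_names is not None else [str(i) for i in range(n_genes)]
    if n_genes < 3:
        logger.warning("robust filter skipped: %d genes (< 3)", n_genes)
        return np.arange(n_genes), OutlierReport(z_max=z_max)
    if weights is None:
        w = np.ones(n_genes)
    else:
        w = np.abs(np.asarray(weights, dtype=float))

    loo = np.empty(n_genes)
    keep_mask = np.ones(n_genes, dtype=bool)
    for i in range(n_genes):
        rows = np.delete(np.arange(n_genes), i)
        fit = fit_pc1(
            X[rows], w[rows], mode=mode, center=center, seed=seed, tol=tol, max_iter=max_iter
        )
        loo[i] = fit.L1
    sd = float(np.std(loo, ddof=1))
    if sd == 0.0:
        z = np.zeros(n_genes)
    else:
        z = (loo - loo.mean()) / sd
        keep_mask = np.abs(z) <= z_max
    removed = [names[i] for i in range(n_genes) if not keep_mask[i]]
    if removed:
        logger.info("robust filter removed %d gene(s): %s", len(removed), ", ".join(removed))
    report = OutlierReport(removed_genes=removed, loo_L1=loo, z_values=z, z_max=z_max)
    return np.flatnonzero(keep_mask), report
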