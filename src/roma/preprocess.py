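"""Expression preprocessing: centering, the global center, low-rank imputation.

Row centering makes every gene's expression sum to zero across samples, the
normalisation assumed by the rank-1 module model (otherwise PC1 tends to
capture basal expression level rather than variation).  Double-centering
additionally zeroes per-sample offsets, but cannot hold for every gene subset
simultaneously, so it is optional.  Missing entries are imputed by fitting a
complete low-rank approximation (per-sample intercept plus ``k_rank``
components) to the observed cells by alternating least squares.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ExpressionMatrix
from .exceptions import RomaError

logger = logging.getLogger(__name__)


def center_rows(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean (over observed entries) from its row."""
    if X.n_samples < 1:
        raise RomaError("matrix has no samples")
    obs = ~X.missing_mask
    counts = obs.sum(axis=1)
    if (counts == 0).any():
        gene = X.gene_ids[int(np.argmax(counts == 0))]
        raise RomaError(f"gene {gene!r} has no observed entries")
    vals = np.where(obs, X.values, 0.0)
    means = vals.sum(axis=1) / counts
    centered = np.where(obs, X.values - means[:, None], np.nan)
    return ExpressionMatrix(centered, X.gene_ids, X.sample_ids, X.missing_mask.copy())


def double_center(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove row means, column means and add back the grand mean.

    Requires a complete matrix (run after imputation); afterwards every row
    sum and every column sum is zero.
    """
    if X.has_missing:
        raise RomaError("double centering requires a complete matrix; impute first")
    v = X.values
    out = v - v.mean(axis=1, keepdims=True) - v.mean(axis=0, keepdims=True) + v.mean()
    return ExpressionMatrix(out, X.gene_ids, X.sample_ids)


def global_center(X: ExpressionMatrix) -> np.ndarray:
    """Per-sample mean over *all* dataset genes — the fixed center C_s.

    This is the central point of the global data distribution through which
    fixed-center PC1s are constrained to pass; it is computed on the full
    matrix, never module-restricted.
    """
    if X.n_genes == 0 or X.n_samples == 0:
        raise RomaError("cannot compute the global center of an empty matrix")
    if X.has_missing:
        raise RomaError("global center requires a complete matrix; impute first")
    return X.values.mean(axis=0)


def impute_missing(
    X: ExpressionMatrix,
    k_rank: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ExpressionMatrix:
    """Fill missing entries from a rank-``k_rank`` fit to the observed cells.

    The model is a per-sample intercept plus ``k_rank`` multiplicative
    components, ``X[g, s] ~ B[s] + sum_k U[g, k] V[s, k]``, fitted by
    alternating least squares restricted to observed entries (each gene row
    and each sample column has a closed-form update).  Iteration stops when
    the relative Frobenius change of the reconstruction drops below ``tol``.
    Observed entries are returned untouched.
    """
    if not X.has_missing:
        return X.copy()
    if k_rank < 1:
        raise ValueError("k_rank must be >= 1")
    if k_rank >= min(X.shape):
        raise ValueError(f"k_rank={k_rank} must be < min(n_genes, n_samples)={min(X.shape)}")
    obs = ~X.missing_mask
    if (obs.sum(axis=1) == 0).any():
        gene = X.gene_ids[int(np.argmax(obs.sum(axis=1) == 0))]
        raise RomaError(f"gene {gene!r} is entirely missing; cannot impute")
    if (obs.sum(axis=0) == 0).any():
        sample = X.sample_ids[int(np.argmax(obs.sum(axis=0) == 0))]
        raise RomaError(f"sample {sample!r} is entirely missing; cannot impute")

    v = X.values
    n_genes, n_samples = X.shape

    # warm start: observed column means as intercept, truncated SVD of the
    # mean-filled residual for the components
    B = np.where(obs, v, 0.0).sum(axis=0) / obs.sum(axis=0)
    resid0 = np.where(obs, v - B[None, :], 0.0)
    U_full, s_full, Vt_full = np.linalg.svd(resid0, full_matrices=False)
    U = U_full[:, :k_rank] * s_full[:k_rank]
    V = Vt_full[:k_rank].T

    recon = B[None, :] + U @ V.T
    for _ in range(max_iter):
        # intercept from observed residuals
        B = np.where(obs, v - U @ V.T, 0.0).sum(axis=0) / obs.sum(axis=0)
        target = v - B[None, :]
        for g in range(n_genes):
            cols = obs[g]
            U[g] = np.linalg.lstsq(V[cols], target[g, cols], rcond=None)[0]
        for s in range(n_samples):
            rows = obs[:, s]
            V[s] = np.linalg.lstsq(U[rows], target[rows, s], rcond=None)[0]
        new_recon = B[None, :] + U @ V.T
        denom = np.linalg.norm(recon)
        change = np.linalg.norm(new_recon - recon) / (denom if denom > 0 else 1.0)
        recon = new_recon
        if change < tol:
            break
    else:
        logger.warning(
            "imputation did not converge in %d iterations (last change %.3g); "
            "returning current estimate", max_iter, change,
        )

    filled = np.where(obs, v, recon)
    return ExpressionMatrix(filled, X.gene_ids, X.sample_ids)
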