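"""Independent reference computations used to check the iterative engine.

These deliberately avoid the package's own code paths: explained-variance
fractions come from a dense eigendecomposition of the exact (weighted,
appropriately centered) covariance, and the two-sample KS statistic from a
brute-force empirical-CDF scan.
"""

from __future__ import annotations

import numpy as np


def dense_variance_fractions(
    X: np.ndarray,
    weights: np.ndarray | None = None,
    mode: str = "standard",
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Eigenvalue fractions of the weighted second-moment matrix.

    Standard mode centers each sample (column over genes) by the weighted
    gene mean; fixed-center mode subtracts the supplied center and nothing
    else.
    """
    X = np.asarray(X, dtype=float)
    w = np.ones(X.shape[0]) if weights is None else np.abs(np.asarray(weights, float))
    if mode == "standard":
        B = (w @ X) / w.sum()
        Xc = X - B[None, :]
    elif mode == "fixed_center":
        Xc = X - np.asarray(center, float)[None, :]
    else:
        raise ValueError(mode)
    S = Xc.T @ (w[:, None] * Xc)
    ev = np.sort(np.linalg.eigvalsh(S))[::-1]
    ev = np.clip(ev, 0.0, None)
    return ev / ev.sum()


def ks_two_sample_brute(a: np.ndarray, b: np.ndarray) -> float:
    """Max gap between the two empirical CDFs, scanned over all data points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    d = 0.0
    for x in np.concatenate([a, b]):
        fa = np.searchsorted(a, x, side="right") / a.size
        fb = np.searchsorted(b, x, side="right") / b.size
        d = max(d, abs(fa - fb))
    return d
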