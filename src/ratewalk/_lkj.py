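"""Unconstrained parameterization of correlation matrices.

A k x k correlation matrix is represented by its canonical partial
correlations (CPCs): each unconstrained parameter u maps to a CPC
z = tanh(u) in (-1, 1), and the CPCs fill the strict lower triangle of the
Cholesky factor row by row.  Placing independent scaled-Beta priors on the
CPCs — shape ``eta + (k - 1 - j) / 2`` for a CPC in (1-based) column j —
induces exactly the LKJ(eta) distribution on the correlation matrix, which
keeps the prior density over u in closed form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_free", "tril_indices", "build_cholesky", "log_cpc_prior",
           "chol_to_corr"]


def n_free(k: int) -> int:
    return k * (k - 1) // 2


def tril_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict lower triangle, row-major order."""
    return np.tril_indices(k, k=-1)


def build_cholesky(u: np.ndarray, k: int) -> np.ndarray:
    """Map unconstrained ``u`` of shape (..., k(k-1)/2) to Cholesky factors.

    Returns an array of shape (..., k, k), lower triangular with unit-norm
    rows, so ``L @ L.T`` is a correlation matrix.
    """
    u = np.asarray(u, dtype=float)
    batch = u.shape[:-1]
    if u.shape[-1] != n_free(k):
        raise ValueError(f"expected {n_free(k)} free parameters for k={k}")
    z = np.tanh(u)
    L = np.zeros(batch + (k, k))
    L[..., 0, 0] = 1.0
    pos = 0
    for i in range(1, k):
        remaining = np.ones(batch)
        for j in range(i):
            zij = z[..., pos]
            L[..., i, j] = zij * np.sqrt(remaining)
            remaining = remaining * (1.0 - zij * zij)
            pos += 1
        L[..., i, i] = np.sqrt(remaining)
    return L


def log_cpc_prior(u: np.ndarray, k: int, shape: float) -> np.ndarray:
    """Log prior density over u inducing LKJ(shape) on the correlation.

    Up to an additive constant: sum over CPCs of b * log(1 - tanh(u)^2)
    with b = shape + (k - 1 - j)/2 for column j (1-based); the extra power
    of (1 - z^2) relative to the Beta density is the tanh Jacobian.
    """
    u = np.asarray(u, dtype=float)
    _, cols = tril_indices(k)
    b = shape + (k - 1.0 - (cols + 1)) / 2.0
    # Beta exponent (b-1) plus one power of (1 - z^2) from the tanh
    # Jacobian gives b * log(1 - tanh(u)^2), computed stably as
    # 2*(log 2 - u - softplus(-2u)).
    log1mz2 = 2.0 * (np.log(2.0) - u - np.logaddexp(0.0, -2.0 * u))
    return np.sum(b * log1mz2, axis=-1)


def chol_to_corr(L: np.ndarray) -> np.ndarray:
    """Correlation matrices from Cholesky factors, batched."""
    return L @ np.swapaxes(L, -1, -2)
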