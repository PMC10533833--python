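"""Warm-started penalized path solvers used by the network estimators.

Both estimation routines reduce to many small L1 problems along a lambda
path, re-solved thousands of times inside permutation and bootstrap
loops, so the inner loops are numba-compiled and operate on Gram
matrices only:

* :func:`lasso_path_gram` — coordinate-descent lasso over a decreasing
  lambda grid, warm-started, given the predictor Gram matrix G = Z'Z/n
  and covariance vector c = Z'y/n.
* :func:`glasso_path` — graphical lasso (blockwise coordinate descent;
  each column update is itself a Gram lasso) over a decreasing grid,
  warm-started across lambdas.  The diagonal is not penalized, matching
  the usual partial-correlation-network convention; solutions agree with
  sklearn.covariance.graphical_lasso to solver tolerance (cross-checked
  in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lasso_path_gram", "glasso_path", "glasso"]


@njit(cache=True)
def _lasso_cd_gram(G, c, lam, b, max_iter, tol):
    """Minimize  ½ b'Gb − c'b + lam·|b|₁  by cyclic coordinate descent.

    ``b`` is updated in place (warm start).  Returns iterations used.
    """
    p = G.shape[0]
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gj = G[j, j]
            if gj <= 0.0:
                continue
            # partial residual correlation for coordinate j
            r = c[j] - (G[j] @ b) + gj * b[j]
            old = b[j]
            if r > lam:
                b[j] = (r - lam) / gj
            elif r < -lam:
                b[j] = (r + lam) / gj
            else:
                b[j] = 0.0
            d = abs(b[j] - old)
            if d > max_delta:
                max_delta = d
        if max_delta < tol:
            return it + 1
    return max_iter


@njit(cache=True)
def _lasso_path_gram_impl(G, c, grid, max_iter, tol):
    p = G.shape[0]
    n_lam = grid.shape[0]
    coefs = np.zeros((n_lam, p))
    b = np.zeros(p)
    for a in range(n_lam):
        _lasso_cd_gram(G, c, grid[a], b, max_iter, tol)
        coefs[a] = b
    return coefs


def lasso_path_gram(
    G: np.ndarray, c: np.ndarray, grid: np.ndarray,
    max_iter: int = 1000, tol: float = 1e-7,
) -> np.ndarray:
    """Lasso coefficients for each lambda of a decreasing grid.

    Returns an (n_lambda, p) array; row a solves
    ½ b'Gb − c'b + grid[a]·|b|₁, warm-started from the previous lambda.
    """
    grid = np.ascontiguousarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be decreasing")
    return _lasso_path_gram_impl(
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(c, dtype=np.float64),
        grid, max_iter, tol,
    )


@njit(cache=True)
def _glasso_impl(S, lam, W, B, max_iter, inner_max_iter, tol, inner_tol):
    """Blockwise graphical lasso; W (covariance) and B (per-column lasso
    coefficients) updated in place for warm starts.  Returns 1 on
    convergence, 0 otherwise."""
    p = S.shape[0]
    off_mean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_mean += abs(S[i, j])
                cnt += 1
    thresh = tol * (off_mean / cnt if cnt > 0 else 1.0)
    if thresh <= 0.0:
        thresh = tol

    G = np.empty((p - 1, p - 1))
    cvec = np.empty(p - 1)
    b = np.empty(p - 1)
    converged = 0
    for _ in range(max_iter):
        max_delta = 0.0
        for col in range(p):
            # build the (p-1) subproblem excluding `col`
            ii = 0
            for i in range(p):
                if i == col:
                    continue
                jj = 0
                for j in range(p):
                    if j == col:
                        continue
                    G[ii, jj] = W[i, j]
                    jj += 1
                cvec[ii] = S[i, col]
                b[ii] = B[col, ii]
                ii += 1
            _lasso_cd_gram(G, cvec, lam, b, inner_max_iter, inner_tol)
            # w12 = W11 b
            ii = 0
            for i in range(p):
                if i == col:
                    continue
                w_new = 0.0
                jj = 0
                for j in range(p):
                    if j == col:
                        continue
                    w_new += W[i, j] * b[jj]
                    jj += 1
                d = abs(w_new - W[i, col])
                if d > max_delta:
                    max_delta = d
                W[i, col] = w_new
                W[col, i] = w_new
                B[col, ii] = b[ii]
                ii += 1
        if max_delta < thresh:
            converged = 1
            break
    return converged


@njit(cache=True)
def _precision_from_blocks(W, B):
    p = W.shape[0]
    theta = np.zeros((p, p))
    for col in range(p):
        dot = 0.0
        ii = 0
        for i in range(p):
            if i == col:
                continue
            dot += W[i, col] * B[col, ii]
            ii += 1
        t22 = 1.0 / max(W[col, col] - dot, 1e-12)
        theta[col, col] = t22
        ii = 0
        for i in range(p):
            if i == col:
                continue
            theta[i, col] = -B[col, ii] * t22
            ii += 1
    # symmetrize (numerically asymmetric by solver tolerance); exact zeros
    # are preserved because both triangles are zero together at convergence
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (theta[i, j] + theta[j, i])
            if theta[i, j] == 0.0 or theta[j, i] == 0.0:
                v = 0.0
            theta[i, j] = v
            theta[j, i] = v
    return theta


def glasso(
    S: np.ndarray, lam: float,
    W: np.ndarray | None = None, B: np.ndarray | None = None,
    max_iter: int = 100, tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One graphical-lasso solve; returns (precision, covariance, W, B).

    Pass the returned ``W``/``B`` back in to warm-start the next (smaller)
    lambda.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if W is None:
        W = S.copy()
    if B is None:
        B = np.zeros((p, p - 1))
    _glasso_impl(S, float(lam), W, B, max_iter, 200, tol, 1e-7)
    theta = _precision_from_blocks(W, B)
    return theta, W.copy(), W, B


def glasso_path(
    S: np.ndarray, grid: np.ndarray, max_iter: int = 100, tol: float = 1e-4,
):
    """Yield (lambda, precision) along a decreasing grid with warm starts."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be decreasing")
    W = None
    B = None
    for lam in grid:
        theta, _, W, B = glasso(S, lam, W=W, B=B, max_iter=max_iter, tol=tol)
        yield float(lam), theta
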