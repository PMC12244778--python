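"""Numba-compiled graphical-lasso core.

Block coordinate descent on the covariance (Friedman-style): each column of
the working covariance W is updated by solving an L1-penalized regression via
coordinate descent.  The penalty applies to off-diagonal entries only, so at
lambda = 0 the solver converges to the plain inverse of S.  Kept free of
Python objects so the whole path can be evaluated inside hot loops
(bootstraps, permutation tests).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def glasso_cd(S, lam, tol, max_iter):
    """Solve min -log det(Omega) + tr(S Omega) + lam * sum_offdiag |omega_ij|.

    Returns (W, B, n_iter, converged): W the estimated covariance, B the
    per-column regression coefficients (B[k, j] multiplies variable k in the
    update of column j; the sparsity pattern of B is the edge pattern).
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    n_iter = 0
    converged = False
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            # inner lasso: beta = argmin 0.5 b'W11 b - s12'b + lam |b|_1
            for _inner in range(1000):
                inner_change = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    # residual gradient excluding coordinate k
                    m = 0.0
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        m += W[k, l] * B[l, j]
                    r = S[k, j] - m
                    bk = 0.0
                    if r > lam:
                        bk = (r - lam) / W[k, k]
                    elif r < -lam:
                        bk = (r + lam) / W[k, k]
                    d = abs(bk - B[k, j])
                    if d > inner_change:
                        inner_change = d
                    B[k, j] = bk
                if inner_change < tol * 0.1:
                    break
            # w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > max_change:
                    max_change = d
                W[k, j] = w
                W[j, k] = w
        n_iter = it + 1
        if max_change < tol:
            converged = True
            break
    return W, B, n_iter, converged


@njit(cache=True)
def precision_from_w(W, B):
    """Recover Omega from the converged covariance W and coefficients B."""
    p = W.shape[0]
    omega = np.zeros((p, p))
    for j in range(p):
        wb = 0.0
        for k in range(p):
            if k != j:
                wb += W[k, j] * B[k, j]
        ojj = 1.0 / (W[j, j] - wb)
        omega[j, j] = ojj
        for k in range(p):
            if k != j:
                omega[k, j] = -B[k, j] * ojj
    # symmetrize, keeping exact zeros where both coefficients vanished
    for i in range(p):
        for j in range(i + 1, p):
            if B[i, j] == 0.0 and B[j, i] == 0.0:
                omega[i, j] = 0.0
                omega[j, i] = 0.0
            else:
                v = 0.5 * (omega[i, j] + omega[j, i])
                omega[i, j] = v
                omega[j, i] = v
    return omega


@njit(cache=True)
def glasso_path(S, lambdas, tol, max_iter):
    """Warm-started glasso along a decreasing penalty path.

    Returns (omegas, ok) with omegas of shape (len(lambdas), p, p) and ok the
    per-lambda convergence flags.
    """
    p = S.shape[0]
    m = lambdas.shape[0]
    omegas = np.zeros((m, p, p))
    ok = np.zeros(m, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p))
    for t in range(m):
        lam = lambdas[t]
        W, B, _, conv = _glasso_warm(S, lam, tol, max_iter, W, B)
        omegas[t] = precision_from_w(W, B)
        ok[t] = conv
    return omegas, ok


@njit(cache=True)
def _glasso_warm(S, lam, tol, max_iter, W0, B0):
    p = S.shape[0]
    W = W0.copy()
    for i in range(p):
        W[i, i] = S[i, i]
    B = B0.copy()
    converged = False
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            for _inner in range(1000):
                inner_change = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    m = 0.0
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        m += W[k, l] * B[l, j]
                    r = S[k, j] - m
                    bk = 0.0
                    if r > lam:
                        bk = (r - lam) / W[k, k]
                    elif r < -lam:
                        bk = (r + lam) / W[k, k]
                    d = abs(bk - B[k, j])
                    if d > inner_change:
                        inner_change = d
                    B[k, j] = bk
                if inner_change < tol * 0.1:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > max_change:
                    max_change = d
                W[k, j] = w
                W[j, k] = w
        if max_change < tol:
            converged = True
            break
    return W, B, 0, converged
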