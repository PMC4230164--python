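"""Small-problem two-class soft-margin SVM solver, batched over problems.

The searchlight solves an enormous number of tiny C-SVC problems (here,
16 samples per sphere, 8 cross-validation folds, one problem per brain
voxel). This module solves the standard LIBSVM dual

    min_a  1/2 a' Q a - e' a,   0 <= a_i <= C,   y' a = 0,
    Q_ij = y_i y_j K(x_i, x_j)

by sequential minimal optimization with maximal-violating-pair working-set
selection, vectorized so that thousands of problems sharing one label vector
advance in lockstep. With precomputed linear kernels this reproduces the
classifier used by LIBSVM / sklearn.SVC(kernel="linear") (the test suite
checks prediction-level agreement) while amortizing the per-problem overhead
that makes a per-sphere sklearn call infeasible at whole-brain scale.

Convention: labels are +/-1; decision value f(x) = sum_i a_i y_i K(x_i, x) - rho,
predict +1 iff f > 0. Ties (f == 0) go to the -1 class, which callers map to
the lexicographically first category.
"""

from __future__ import annotations

import numpy as np

_TAU = 1e-12


def solve_csvc(K: np.ndarray, y: np.ndarray, C: float = 1.0,
               tol: float = 1e-6, max_iter: int = 10_000
               ) -> tuple[np.ndarray, np.ndarray]:
    """Solve a batch of C-SVC duals sharing the label vector ``y``.

    Parameters
    ----------
    K : (V, n, n) or (n, n) precomputed kernel matrices.
    y : (n,) labels in {+1, -1}.
    C : box constraint.
    tol : KKT violation stopping tolerance. Tighter than LIBSVM's 1e-3
        default so that decision-value signs are solver-independent except
        on genuine (measure-zero) ties.

    Returns
    -------
    alpha : (V, n) dual coefficients; rho : (V,) intercepts.
    """
    K = np.asarray(K, dtype=float)
    single = K.ndim == 2
    if single:
        K = K[None]
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape[1:] != (n, n):
        raise ValueError(f"kernel shape {K.shape} does not match {n} labels")
    if not np.all(np.isin(y, (-1.0, 1.0))) or len(np.unique(y)) != 2:
        raise ValueError("labels must contain both +1 and -1")
    V = K.shape[0]

    alpha = np.zeros((V, n))
    grad = np.full((V, n), -1.0)
    active = np.arange(V)
    yy = y[None, :]

    for _ in range(max_iter):
        if active.size == 0:
            break
        g = grad[active]
        a = alpha[active]
        b = -yy * g  # -y_i * grad_i
        up = np.where(yy > 0, a < C - _TAU, a > _TAU)
        low = np.where(yy > 0, a > _TAU, a < C - _TAU)
        b_up = np.where(up, b, -np.inf)
        b_low = np.where(low, b, np.inf)
        i = np.argmax(b_up, axis=1)
        j = np.argmin(b_low, axis=1)
        r = np.arange(active.size)
        viol = b_up[r, i] - b_low[r, j]
        done = viol < tol
        if done.any():
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            a, g = a[keep], g[keep]
            i, j, viol = i[keep], j[keep], viol[keep]
            r = np.arange(active.size)

        Ka = K[active]
        Kii = Ka[r, i, i]
        Kjj = Ka[r, j, j]
        Kij = Ka[r, i, j]
        quad = np.maximum(Kii + Kjj - 2.0 * Kij, _TAU)
        d = viol / quad
        yi, yj = y[i], y[j]
        room_i = np.where(yi > 0, C - a[r, i], a[r, i])
        room_j = np.where(yj > 0, a[r, j], C - a[r, j])
        d = np.minimum(d, np.minimum(room_i, room_j))

        alpha[active, i] += yi * d
        alpha[active, j] -= yj * d
        # Q[:, i] * dalpha_i + Q[:, j] * dalpha_j with dalpha_i = y_i d,
        # dalpha_j = -y_j d and Q_ti = y_t y_i K_ti reduces to d * y * (K_i - K_j)
        grad[active] += d[:, None] * yy * (Ka[r, :, i] - Ka[r, :, j])

    rho = _calculate_rho(alpha, grad, y, C)
    if single:
        return alpha[0], rho[0]
    return alpha, rho


def _calculate_rho(alpha: np.ndarray, grad: np.ndarray, y: np.ndarray,
                   C: float) -> np.ndarray:
    """LIBSVM's rho rule: average y*grad over free vectors, else bound midpoint."""
    yG = y[None, :] * grad
    free = (alpha > _TAU) & (alpha < C - _TAU)
    nfree = free.sum(axis=1)
    with np.errstate(invalid="ignore"):
        rho_free = np.where(free, yG, 0.0).sum(axis=1) / nfree
    at_upper = alpha >= C - _TAU
    at_lower = alpha <= _TAU
    ub_mask = (at_upper & (y[None, :] < 0)) | (at_lower & (y[None, :] > 0))
    lb_mask = (at_upper & (y[None, :] > 0)) | (at_lower & (y[None, :] < 0))
    ub = np.where(ub_mask, yG, np.inf).min(axis=1)
    lb = np.where(lb_mask, yG, -np.inf).max(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(nfree > 0, rho_free, 0.5 * (ub + lb))


def decision_values(K_cross: np.ndarray, alpha: np.ndarray, y: np.ndarray,
                    rho: np.ndarray) -> np.ndarray:
    """Decision values for test points.

    ``K_cross``: (V, n_test, n_train) kernels between test and train samples.
    Returns (V, n_test).
    """
    coef = alpha * y[None, :]
    return np.einsum("vtn,vn->vt", K_cross, coef) - rho[:, None]
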