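"""Kernel-space epsilon-SVR solver (SMO with second-order working-set selection).

This is the classic libsvm solver specialized to epsilon-SVR with a
precomputed kernel, compiled with numba so that the LOOCV/permutation engine
can afford hundreds of thousands of small fits. The dual is solved in the
expanded 2n-variable form (alpha, alpha*), with the same working-set
selection, pair update, stopping rule (max violating pair gap < tol) and
intercept (rho) computation as libsvm; unit tests check agreement with
sklearn.svm.SVR to solver tolerance.

The decision function is f(x) = sum_t beta_t K(x_t, x) + b with
beta = alpha - alpha* and b = -rho; for a linear kernel the primal weights
are w = X^T beta.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU = 1e-12


@njit(cache=True, fastmath=False)
def solve_svr_kernel_ws(K, y, C, eps, tol, max_iter, beta0):  # pragma: no cover
    """Solve epsilon-SVR on a precomputed kernel matrix, warm-started at beta0.

    beta0 must be feasible: entries in [-C, C] and summing to ~0 (the SMO
    pair updates preserve the equality constraint, so an infeasible start
    would converge to the wrong solution). Returns (beta, rho, n_iter);
    intercept is -rho.
    """
    n = K.shape[0]
    N = 2 * n
    a = np.zeros(N)
    cold = True
    for t in range(n):
        if beta0[t] != 0.0:
            cold = False
        if beta0[t] > 0.0:
            a[t] = beta0[t]
        elif beta0[t] < 0.0:
            a[t + n] = -beta0[t]
    g = np.empty(N)
    if cold:
        for t in range(n):
            g[t] = eps - y[t]
            g[t + n] = eps + y[t]
    else:
        # g = Q a + p recomputed from the base kernel: q = K beta
        for t in range(n):
            q = 0.0
            for s in range(n):
                q += K[t, s] * beta0[s]
            g[t] = q + eps - y[t]
            g[t + n] = -q + eps + y[t]

    Kd = np.empty(n)
    for t in range(n):
        Kd[t] = K[t, t]

    it = 0
    while it < max_iter:
        # --- first element: maximal violating index in I_up ---
        Gmax = -1e300
        i = -1
        for t in range(n):  # sign +1 half
            if a[t] < C and -g[t] >= Gmax:
                Gmax = -g[t]
                i = t
        for t in range(n):  # sign -1 half
            if a[t + n] > 0.0 and g[t + n] >= Gmax:
                Gmax = g[t + n]
                i = t + n
        if i == -1:
            break
        ib = i if i < n else i - n
        si = 1.0 if i < n else -1.0
        Ki = K[ib]
        Kii = Ki[ib]

        # --- second element: best decrease among I_low (second-order rule) ---
        Gmax2 = -1e300
        j = -1
        obj_min = 1e300
        for t in range(n):  # sign +1 half: in I_low when a > 0
            if a[t] > 0.0:
                gt = g[t]
                if gt >= Gmax2:
                    Gmax2 = gt
                grad_diff = Gmax + gt
                if grad_diff > 0.0:
                    quad = Kii + Kd[t] - 2.0 * Ki[t]
                    if quad <= 0.0:
                        quad = TAU
                    obj = -(grad_diff * grad_diff) / quad
                    if obj <= obj_min:
                        obj_min = obj
                        j = t
        for t in range(n):  # sign -1 half: in I_low when a < C
            if a[t + n] < C:
                gt = g[t + n]
                if -gt >= Gmax2:
                    Gmax2 = -gt
                grad_diff = Gmax - gt
                if grad_diff > 0.0:
                    quad = Kii + Kd[t] - 2.0 * Ki[t]
                    if quad <= 0.0:
                        quad = TAU
                    obj = -(grad_diff * grad_diff) / quad
                    if obj <= obj_min:
                        obj_min = obj
                        j = t + n
        if Gmax + Gmax2 < tol or j == -1:
            break

        jb = j if j < n else j - n
        sj = 1.0 if j < n else -1.0
        quad = Kii + Kd[jb] - 2.0 * Ki[jb]
        if quad <= 0.0:
            quad = TAU

        old_ai = a[i]
        old_aj = a[j]
        if si != sj:
            delta = (-g[i] - g[j]) / quad
            diff = a[i] - a[j]
            a[i] += delta
            a[j] += delta
            if diff > 0.0:
                if a[j] < 0.0:
                    a[j] = 0.0
                    a[i] = diff
            else:
                if a[i] < 0.0:
                    a[i] = 0.0
                    a[j] = -diff
            if diff > 0.0:
                if a[i] > C:
                    a[i] = C
                    a[j] = C - diff
            else:
                if a[j] > C:
                    a[j] = C
                    a[i] = C + diff
        else:
            delta = (g[i] - g[j]) / quad
            ssum = a[i] + a[j]
            a[i] -= delta
            a[j] += delta
            if ssum > C:
                if a[i] > C:
                    a[i] = C
                    a[j] = ssum - C
            else:
                if a[j] < 0.0:
                    a[j] = 0.0
                    a[i] = ssum
            if ssum > C:
                if a[j] > C:
                    a[j] = C
                    a[i] = ssum - C
            else:
                if a[i] < 0.0:
                    a[i] = 0.0
                    a[j] = ssum

        dai = si * (a[i] - old_ai)
        daj = sj * (a[j] - old_aj)
        Kj = K[jb]
        for t in range(n):
            upd = Ki[t] * dai + Kj[t] * daj
            g[t] += upd
            g[t + n] -= upd
        it += 1

    # --- intercept via libsvm's rho rule on the expanded problem ---
    ub = 1e300
    lb = -1e300
    sum_free = 0.0
    nr_free = 0
    for t in range(N):
        s = 1.0 if t < n else -1.0
        yG = s * g[t]
        if a[t] >= C:
            if s < 0.0:
                if yG < ub:
                    ub = yG
            else:
                if yG > lb:
                    lb = yG
        elif a[t] <= 0.0:
            if s > 0.0:
                if yG < ub:
                    ub = yG
            else:
                if yG > lb:
                    lb = yG
        else:
            nr_free += 1
            sum_free += yG
    if nr_free > 0:
        rho = sum_free / nr_free
    else:
        rho = (ub + lb) / 2.0

    beta = a[:n] - a[n:]
    return beta, rho, it


def solve_svr_kernel(K, y, C, eps, tol, max_iter):
    """Cold-start epsilon-SVR solve; see solve_svr_kernel_ws."""
    return solve_svr_kernel_ws(K, y, C, eps, tol, max_iter, _ZEROS(K.shape[0]))


def _ZEROS(n):
    return np.zeros(n)


def feasible_warm_start(beta_full: np.ndarray, drop: int, C: float) -> np.ndarray:
    """Restrict a full-sample dual solution to a leave-one-out training set.

    Dropping subject ``drop`` leaves the remaining coefficients summing to
    -beta_full[drop]; the residual is redistributed over entries with box
    slack so the start is feasible for the SMO equality constraint.
    """
    beta = np.delete(beta_full, drop)
    r = -float(beta.sum())
    if r != 0.0:
        for t in range(beta.size):
            room = (C - beta[t]) if r > 0 else (-C - beta[t])
            step = r if abs(r) <= abs(room) else room
            beta[t] += step
            r -= step
            if r == 0.0:
                break
    return beta


@njit(cache=True, fastmath=False)
def fold_refit_predict(Xsel, y, hold_out, ks, beta_init, C, eps, tol, max_iter):
    """Nested top-k refits and held-out prediction for one LOOCV fold.

    ``Xsel`` is the full cohort restricted to the fold's top-k_max ranked
    features (columns in rank order), ``ks`` the ascending per-threshold
    feature counts. Sub-Grams accumulate incrementally across the nested
    subsets and each refit warm-starts from the previous one. Returns the
    held-out subject's prediction per threshold (-1 iteration count signals
    non-convergence via the last element of the returned iters array).
    """
    n = Xsel.shape[0]
    m = n - 1
    nk = ks.shape[0]
    preds = np.empty(nk)
    iters = np.empty(nk, dtype=np.int64)
    Gsel = np.zeros((n, n))
    prev = 0
    ytr = np.empty(m)
    for t in range(m):
        ytr[t] = y[t] if t < hold_out else y[t + 1]
    Ktr = np.empty((m, m))
    beta = beta_init.copy()
    for c in range(nk):
        k = ks[c]
        if k > prev:
            chunk = np.ascontiguousarray(Xsel[:, prev:k])
            Gsel += chunk @ chunk.T
            prev = k
        for r in range(m):
            rr = r if r < hold_out else r + 1
            for s in range(m):
                ss = s if s < hold_out else s + 1
                Ktr[r, s] = Gsel[rr, ss]
        beta, rho, it = solve_svr_kernel_ws(Ktr, ytr, C, eps, tol, max_iter, beta)
        iters[c] = it
        acc = 0.0
        for r in range(m):
            rr = r if r < hold_out else r + 1
            acc += Gsel[hold_out, rr] * beta[r]
        preds[c] = acc - rho
    return preds, iters


def svr_fit_kernel(K, y, C=1.0, epsilon=0.1, tol=1e-3, max_iter=2_000_000):
    """Convenience wrapper: returns (beta, intercept, n_iter)."""
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    beta, rho, it = solve_svr_kernel(K, y, C, epsilon, tol, max_iter)
    if it >= max_iter:
        import warnings

        warnings.warn("SVR solver hit max_iter; solution may be inexact", stacklevel=2)
    return beta, -rho, it


def svr_fit_linear(X, y, C=1.0, epsilon=0.1, tol=1e-3):
    """Linear-kernel fit on raw features; returns (weights, intercept)."""
    X = np.asarray(X, dtype=np.float64)
    beta, b, _ = svr_fit_kernel(X @ X.T, y, C=C, epsilon=epsilon, tol=tol)
    return X.T @ beta, b
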