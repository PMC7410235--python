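"""Numba kernels for the elastic-net-penalized logistic solver.

The objective, for standardized X with unpenalized intercept b0, is

    f(b0, beta) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
                  + lam * ( alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2 )

with eta = b0 + X beta.  The solver is proximal Newton: each outer iteration
forms the weighted-least-squares approximation of the logistic loss at the
current fit (IRLS weights w_i = p_i (1 - p_i), floored away from zero) and
minimizes it plus the penalty by cyclic coordinate descent with
soft-thresholding, which yields exact zeros.  Inner sweeps iterate over the
active (nonzero) set and periodically verify with a full sweep.  A
step-halving guard keeps the exact penalized objective non-increasing
across outer iterations — a property the tests assert.  Convergence is
declared when the max KKT (subgradient) violation of the exact objective
falls below ``tol``.

All kernels take the predictor matrix transposed (``XT``, shape p × n,
C-contiguous) so column access is contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

W_FLOOR = 1e-5  # lower clip on IRLS weights, as in standard CD implementations


@njit(cache=True)
def _sigmoid(eta):
    out = np.empty_like(eta)
    for i in range(eta.size):
        v = eta[i]
        if v >= 0.0:
            out[i] = 1.0 / (1.0 + np.exp(-v))
        else:
            e = np.exp(v)
            out[i] = e / (1.0 + e)
    return out


@njit(cache=True)
def _eta(XT, beta, b0):
    n = XT.shape[1]
    eta = np.full(n, b0)
    for j in range(beta.size):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                eta[i] += XT[j, i] * bj
    return eta


@njit(cache=True)
def penalized_objective(XT, y, b0, beta, lam, alpha):
    n = XT.shape[1]
    eta = _eta(XT, beta, b0)
    nll = 0.0
    for i in range(n):
        v = eta[i]
        # log(1 + exp(v)) - y v, computed stably
        if v > 0.0:
            nll += v + np.log1p(np.exp(-v)) - y[i] * v
        else:
            nll += np.log1p(np.exp(v)) - y[i] * v
    l1 = np.sum(np.abs(beta))
    l2 = np.sum(beta * beta)
    return nll / n + lam * (alpha * l1 + (1.0 - alpha) * 0.5 * l2)


@njit(cache=True)
def kkt_violation(XT, y, b0, beta, lam, alpha):
    """Max violation of the stationarity conditions of the exact objective."""
    p, n = XT.shape
    prob = _sigmoid(_eta(XT, beta, b0))
    viol = 0.0
    m = 0.0
    for i in range(n):
        m += prob[i] - y[i]
    viol = abs(m / n)  # unpenalized intercept
    for j in range(p):
        g = 0.0
        for i in range(n):
            g += XT[j, i] * (prob[i] - y[i])
        g = g / n + lam * (1.0 - alpha) * beta[j]
        if beta[j] > 0.0:
            v = abs(g + lam * alpha)
        elif beta[j] < 0.0:
            v = abs(g - lam * alpha)
        else:
            v = max(0.0, abs(g) - lam * alpha)
        if v > viol:
            viol = v
    return viol


@njit(cache=True)
def fit_one(XT, y, lam, alpha, beta, b0, tol, max_iter, active_mask):
    """Proximal-Newton coordinate descent from a warm start; beta updated
    in place.

    ``active_mask[j] = 0`` freezes coordinate j at zero (used for columns
    that are constant within a bootstrap resample).  ``max_iter`` caps the
    total number of inner CD sweeps.  Returns (b0, n_sweeps, converged,
    kkt, obj_trace) where obj_trace holds the exact penalized objective
    after each accepted outer iteration.
    """
    p, n = XT.shape
    thresh = lam * alpha
    # ties at the threshold (e.g. lambda exactly lambda_max) resolve to zero
    tie = thresh + 1e-12 * (1.0 + thresh)
    max_outer = 200
    obj_trace = np.empty(max_outer)
    n_outer = 0
    sweeps = 0
    converged = False
    kkt = np.inf
    eta = _eta(XT, beta, b0)
    f_cur = penalized_objective(XT, y, b0, beta, lam, alpha)
    wxs = np.empty(p)
    in_active = np.zeros(p, dtype=np.bool_)

    while n_outer < max_outer and sweeps < max_iter:
        prob = _sigmoid(eta)
        w = prob * (1.0 - prob)
        wsum = 0.0
        for i in range(n):
            if w[i] < W_FLOOR:
                w[i] = W_FLOOR
            wsum += w[i]
        # working response z; r tracks z - b0 - X beta
        r = (y - prob) / w
        for j in range(p):
            wx = 0.0
            for i in range(n):
                wx += w[i] * XT[j, i] * XT[j, i]
            wxs[j] = wx / n

        beta_old = beta.copy()
        b0_old = b0
        inner_tol = tol * 0.1
        full_pass = True
        # inner CD on the weighted quadratic: active-set sweeps with
        # full-sweep verification
        while sweeps < max_iter:
            sweeps += 1
            max_delta = 0.0
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= wsum
            b0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
            for j in range(p):
                if not active_mask[j]:
                    continue
                if not full_pass and not in_active[j]:
                    continue
                bj = beta[j]
                wxr = 0.0
                for i in range(n):
                    wxr += w[i] * XT[j, i] * r[i]
                num = wxr / n + wxs[j] * bj
                denom = wxs[j] + lam * (1.0 - alpha)
                if denom <= 0.0:
                    continue
                if num > tie:
                    bnew = (num - thresh) / denom
                elif num < -tie:
                    bnew = (num + thresh) / denom
                else:
                    bnew = 0.0
                if bnew != bj:
                    delta = bj - bnew
                    for i in range(n):
                        r[i] += XT[j, i] * delta
                    beta[j] = bnew
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if full_pass:
                for j in range(p):
                    in_active[j] = beta[j] != 0.0
                if max_delta < inner_tol:
                    break  # full sweep converged
                full_pass = False
            elif max_delta < inner_tol:
                full_pass = True  # active set stable; verify with full sweep

        # step-halving guard: accept only non-increasing exact objective
        f_new = penalized_objective(XT, y, b0, beta, lam, alpha)
        halvings = 0
        while f_new > f_cur + 1e-15 and halvings < 30:
            b0 = 0.5 * (b0 + b0_old)
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_old[j])
            f_new = penalized_objective(XT, y, b0, beta, lam, alpha)
            halvings += 1
        if f_new > f_cur + 1e-15:
            # cannot decrease further: revert and stop at the previous point
            b0 = b0_old
            for j in range(p):
                beta[j] = beta_old[j]
            kkt = kkt_violation(XT, y, b0, beta, lam, alpha)
            converged = kkt <= tol
            obj_trace[n_outer] = f_cur
            n_outer += 1
            break
        f_cur = f_new
        obj_trace[n_outer] = f_cur
        n_outer += 1
        eta = _eta(XT, beta, b0)

        kkt = kkt_violation(XT, y, b0, beta, lam, alpha)
        if kkt <= tol:
            converged = True
            break
    if not converged:
        kkt = kkt_violation(XT, y, b0, beta, lam, alpha)
        converged = kkt <= tol
    return b0, sweeps, converged, kkt, obj_trace[:n_outer]


@njit(cache=True)
def fit_path(XT, y, lambdas, alpha, tol, max_iter):
    """Warm-started fits along a decreasing lambda sequence."""
    p = XT.shape[0]
    L = lambdas.size
    betas = np.zeros((L, p))
    intercepts = np.zeros(L)
    n_iters = np.zeros(L, dtype=np.int64)
    conv = np.zeros(L, dtype=np.bool_)
    kkts = np.zeros(L)
    ybar = min(max(np.mean(y), 1e-6), 1.0 - 1e-6)  # single-class-fold safe
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    mask = np.ones(p, dtype=np.bool_)
    for ell in range(L):
        b0, it, cv, kkt, _ = fit_one(
            XT, y, lambdas[ell], alpha, beta, b0, tol, max_iter, mask
        )
        betas[ell] = beta
        intercepts[ell] = b0
        n_iters[ell] = it
        conv[ell] = cv
        kkts[ell] = kkt
    return betas, intercepts, n_iters, conv, kkts
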