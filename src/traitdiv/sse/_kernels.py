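"""Numba kernels for the state-dependent birth-death likelihood.

Per branch, going backward in time, the extinction probabilities E_i and the
data partial likelihoods D_i over the K composite (observed x hidden) states
obey

    dE_i/dt = mu_i - (lam_i + mu_i + sum_j q_ij) E_i + lam_i E_i^2
              + sum_j q_ij E_j
    dD_i/dt = -(lam_i + mu_i + sum_j q_ij) D_i + 2 lam_i E_i D_i
              + sum_j q_ij D_j

integrated here with an adaptive Dormand-Prince 5(4) stepper (the D block is
also available as a K x K fundamental matrix for the marginal-reconstruction
pass, since the D system is linear given E).
"""

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200,
                187 / 2100, 1 / 40])


@njit(cache=True)
def _rhs(y, lam, mu, q, qtot, out):
    K = lam.size
    for i in range(K):
        E = y[i]
        D = y[K + i]
        dE = mu[i] - (lam[i] + mu[i] + qtot[i]) * E + lam[i] * E * E
        dD = -(lam[i] + mu[i] + qtot[i]) * D + 2.0 * lam[i] * E * D
        for j in range(K):
            if q[i, j] > 0.0:
                dE += q[i, j] * y[j]
                dD += q[i, j] * y[K + j]
        out[i] = dE
        out[K + i] = dD


@njit(cache=True)
def integrate_branch(y0, t, lam, mu, q, qtot, rtol, atol):
    """Advance [E, D] over a branch of duration ``t``; returns the end state."""
    n = y0.size
    y = y0.copy()
    if t <= 0.0:
        return y
    ks = np.zeros((7, n))
    ytmp = np.zeros(n)
    yerr = np.zeros(n)
    y5 = np.zeros(n)
    h = t / 10.0
    s = 0.0
    while s < t:
        if h > t - s:
            h = t - s
        _rhs(y, lam, mu, q, qtot, ks[0])
        for stage in range(1, 7):
            for i in range(n):
                acc = 0.0
                for j in range(stage):
                    acc += _A[stage, j] * ks[j, i]
                ytmp[i] = y[i] + h * acc
            _rhs(ytmp, lam, mu, q, qtot, ks[stage])
        errmax = 0.0
        for i in range(n):
            a5 = 0.0
            a4 = 0.0
            for j in range(7):
                a5 += _B5[j] * ks[j, i]
                a4 += _B4[j] * ks[j, i]
            y5[i] = y[i] + h * a5
            yerr[i] = h * (a5 - a4)
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(yerr[i]) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0:
            s += h
            for i in range(n):
                y[i] = y5[i]
            fac = 5.0 if errmax == 0.0 else min(5.0, 0.9 * errmax ** -0.2)
            h *= fac
        else:
            h *= max(0.1, 0.9 * errmax ** -0.2)
        if h < 1e-14 * t:
            # step collapse: bail out, caller checks for NaN
            for i in range(n):
                y[i] = np.nan
            return y
    return y


@njit(cache=True)
def tree_loglik(children, is_tip, brlen, postorder, root, tipD, E0,
                lam, mu, q, qtot, root_mode, condition, rtol, atol):
    """Postorder pruning log-likelihood over the whole tree.

    ``children`` is (n_nodes, 2) with -1 rows for tips; ``tipD`` holds the
    rho-scaled tip initial D rows; ``E0`` the shared 1-rho tip extinction
    start.  ``root_mode``: 0 = FitzJohn weights, 1 = uniform.
    """
    K = lam.size
    n_nodes = brlen.size
    Etop = np.zeros((n_nodes, K))
    Dtop = np.zeros((n_nodes, K))
    logscale = 0.0
    Eroot = np.zeros(K)
    Droot = np.zeros(K)
    y = np.zeros(2 * K)
    for oi in range(postorder.size):
        v = postorder[oi]
        if is_tip[v]:
            for i in range(K):
                y[i] = E0[i]
                y[K + i] = tipD[v, i]
        else:
            c1 = children[v, 0]
            c2 = children[v, 1]
            for i in range(K):
                y[i] = Etop[c1, i]
                y[K + i] = lam[i] * Dtop[c1, i] * Dtop[c2, i]
            s = 0.0
            for i in range(K):
                s += y[K + i]
            if not (s > 0.0) or not np.isfinite(s):
                return -np.inf
            for i in range(K):
                y[K + i] /= s
            logscale += np.log(s)
            if v == root:
                for i in range(K):
                    Eroot[i] = y[i]
                    Droot[i] = y[K + i]
                break
        y = integrate_branch(y, brlen[v], lam, mu, q, qtot, rtol, atol)
        ok = True
        for i in range(2 * K):
            if not np.isfinite(y[i]):
                ok = False
        if not ok:
            return -np.inf
        s = 0.0
        for i in range(K):
            if y[K + i] < 0.0:
                y[K + i] = 0.0
            s += y[K + i]
        if not (s > 0.0):
            return -np.inf
        for i in range(K):
            Etop[v, i] = min(max(y[i], 0.0), 1.0)
            Dtop[v, i] = y[K + i] / s
        logscale += np.log(s)

    sD = 0.0
    for i in range(K):
        sD += Droot[i]
    L = 0.0
    for i in range(K):
        w = Droot[i] / sD if root_mode == 0 else 1.0 / K
        term = Droot[i]
        if condition:
            denom = lam[i] * (1.0 - Eroot[i]) ** 2
            if denom <= 0.0:
                return -np.inf
            term = term / denom
        L += w * term
    if not (L > 0.0):
        return -np.inf
    return np.log(L) + logscale


@njit(cache=True)
def _rhs_prop(y, lam, mu, q, qtot, out):
    """E block plus a K x K fundamental matrix of the linear D system."""
    K = lam.size
    for i in range(K):
        E = y[i]
        dE = mu[i] - (lam[i] + mu[i] + qtot[i]) * E + lam[i] * E * E
        for j in range(K):
            if q[i, j] > 0.0:
                dE += q[i, j] * y[j]
        out[i] = dE
    for col in range(K):
        base = K + col * K
        for i in range(K):
            D = y[base + i]
            dD = -(lam[i] + mu[i] + qtot[i]) * D + 2.0 * lam[i] * y[i] * D
            for j in range(K):
                if q[i, j] > 0.0:
                    dD += q[i, j] * y[base + j]
            out[base + i] = dD


@njit(cache=True)
def branch_propagator(E_init, t, lam, mu, q, qtot, rtol, atol):
    """(E_top, M) with D_top = M @ D_bottom along one branch."""
    K = lam.size
    n = K + K * K
    y = np.zeros(n)
    for i in range(K):
        y[i] = E_init[i]
    for col in range(K):
        y[K + col * K + col] = 1.0
    ks = np.zeros((7, n))
    ytmp = np.zeros(n)
    y5 = np.zeros(n)
    h = t / 10.0 if t > 0 else 0.0
    s = 0.0
    while s < t:
        if h > t - s:
            h = t - s
        _rhs_prop(y, lam, mu, q, qtot, ks[0])
        for stage in range(1, 7):
            for i in range(n):
                acc = 0.0
                for j in range(stage):
                    acc += _A[stage, j] * ks[j, i]
                ytmp[i] = y[i] + h * acc
            _rhs_prop(ytmp, lam, mu, q, qtot, ks[stage])
        errmax = 0.0
        for i in range(n):
            a5 = 0.0
            a4 = 0.0
            for j in range(7):
                a5 += _B5[j] * ks[j, i]
                a4 += _B4[j] * ks[j, i]
            y5[i] = y[i] + h * a5
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(h * (a5 - a4)) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0:
            s += h
            for i in range(n):
                y[i] = y5[i]
            fac = 5.0 if errmax == 0.0 else min(5.0, 0.9 * errmax ** -0.2)
            h *= fac
        else:
            h *= max(0.1, 0.9 * errmax ** -0.2)
        if h < 1e-14 * t:
            for i in range(n):
                y[i] = np.nan
            break
    E_top = np.zeros(K)
    M = np.zeros((K, K))
    for i in range(K):
        E_top[i] = y[i]
    for col in range(K):
        for i in range(K):
            M[i, col] = y[K + col * K + i]
    return E_top, M
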