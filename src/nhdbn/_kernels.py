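"""Jit-compiled numerical core of the per-target sampler.

The chain spends essentially all its time evaluating the closed-form
marginal likelihood of the piecewise regression (once per Metropolis
proposal and twice per coupling-indicator update).  These kernels compute
that quantity, the forward posterior-mean (w~) recursion and the
per-segment Cholesky factors needed for weight draws, for coefficient
dimensions of at most fan-in + 1.  They are pure functions of their
inputs (no random state inside), so the Python driver retains full
control of the random number stream.

The pure-numpy reference implementations live in :mod:`nhdbn.regression`
and :mod:`nhdbn.models`; the two paths are cross-checked in the test
suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_PI = math.log(math.pi)


@njit(cache=True)
def _cholesky(A, L):
    """Lower Cholesky factor of a small SPD matrix, written into L."""
    k = A.shape[0]
    for i in range(k):
        for j in range(i + 1):
            s = A[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                L[i, j] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, k):
            L[i, j] = 0.0


@njit(cache=True)
def _cho_solve(L, b, x):
    """Solve (L L^T) x = b for small lower-triangular L."""
    k = L.shape[0]
    for i in range(k):
        s = b[i]
        for m in range(i):
            s -= L[i, m] * x[m]
        x[i] = s / L[i, i]
    for i in range(k - 1, -1, -1):
        s = x[i]
        for m in range(i + 1, k):
            s -= L[m, i] * x[m]
        x[i] = s / L[i, i]


@njit(cache=True)
def suite(y, X, starts, ends, lam, couple, a_sig, b_sig):
    """Full evaluation of one (parents, tau, theta) configuration.

    Parameters: valid-observation response ``y`` (Tv,), design ``X``
    (Tv, k1) with intercept column, segment bounds ``starts``/``ends``
    into the valid-observation arrays, per-segment prior variance factors
    ``lam`` and coupling indicators ``couple`` (mu_h = couple[h] *
    w~_{h-1}).

    Returns ``(logml, delta2, wtilde, chols)`` where ``wtilde[h]`` is the
    posterior-mean coefficient vector of segment h and ``chols[h]`` the
    lower Cholesky factor of ``Sigma_h^{-1} + X_h^T X_h``.
    """
    H = starts.shape[0]
    k1 = X.shape[1]
    wtilde = np.zeros((H, k1))
    chols = np.zeros((H, k1, k1))
    G = np.zeros((k1, k1))
    A = np.zeros((k1, k1))
    b = np.zeros(k1)
    u = np.zeros(k1)
    z = np.zeros(k1)
    rhs = np.zeros(k1)
    wt_prev = np.zeros(k1)
    delta2 = 0.0
    logdet = 0.0
    T = 0
    for h in range(H):
        s, e = starts[h], ends[h]
        Th = e - s
        T += Th
        yy = 0.0
        for i in range(k1):
            b[i] = 0.0
            for j in range(k1):
                G[i, j] = 0.0
        for t in range(s, e):
            yy += y[t] * y[t]
            for i in range(k1):
                b[i] += X[t, i] * y[t]
                for j in range(i, k1):
                    G[i, j] += X[t, i] * X[t, j]
        for i in range(k1):
            for j in range(i):
                G[i, j] = G[j, i]
        inv_lam = 1.0 / lam[h]
        for i in range(k1):
            for j in range(k1):
                A[i, j] = G[i, j]
            A[i, i] += inv_lam
        L = chols[h]
        _cholesky(A, L)
        ld = 0.0
        for i in range(k1):
            ld += math.log(L[i, i])
        logdet += 2.0 * ld + k1 * math.log(lam[h])
        # prior mean of this segment
        c = float(couple[h])
        quad = yy
        for i in range(k1):
            mu_i = c * wt_prev[i]
            gm = 0.0
            for j in range(k1):
                gm += G[i, j] * (c * wt_prev[j])
            u[i] = b[i] - gm
            quad += mu_i * (gm - 2.0 * b[i])
            rhs[i] = mu_i * inv_lam + b[i]
        _cho_solve(L, u, z)
        for i in range(k1):
            quad -= u[i] * z[i]
        if quad < 0.0:
            quad = 0.0
        delta2 += quad
        _cho_solve(L, rhs, z)
        for i in range(k1):
            wtilde[h, i] = z[i]
            wt_prev[i] = z[i]
    logml = (
        math.lgamma(0.5 * T + a_sig)
        - math.lgamma(a_sig)
        - 0.5 * T * LOG_PI
        + a_sig * math.log(2.0 * b_sig)
        - 0.5 * logdet
        - (0.5 * T + a_sig) * math.log(2.0 * b_sig + delta2)
    )
    return logml, delta2, wtilde, chols


@njit(cache=True)
def draw_weights(chols, wtilde, Z, sigma):
    """Transform iid standard normals Z into weight draws.

    w_h = w~_h + sigma * L_h^{-T} z_h  with  A_h = L_h L_h^T.
    """
    H, k1 = wtilde.shape
    W = np.zeros((H, k1))
    for h in range(H):
        L = chols[h]
        for i in range(k1 - 1, -1, -1):
            s = Z[h, i]
            for m in range(i + 1, k1):
                s -= L[m, i] * W[h, m]
            W[h, i] = s / L[i, i]
        for i in range(k1):
            W[h, i] = wtilde[h, i] + sigma * W[h, i]
    return W


@njit(cache=True)
def _log_delta_prior(couple, a, b):
    """Beta-Bernoulli marginal prior of couple[1:] (couple[0] is fixed 0)."""
    H = couple.shape[0]
    s = 0
    for h in range(1, H):
        s += couple[h]
    f = (H - 1) - s
    return (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + math.lgamma(a + s)
        + math.lgamma(b + f)
        - math.lgamma(a + b + (H - 1))
    )


@njit(cache=True)
def update_deltas(
    y, X, starts, ends, couple, lam_u, lam_c, a, b, a_sig, b_sig, unifs
):
    """Collapsed Gibbs sweep over the coupling indicators of segments 2..H.

    ``couple`` (int8, length H, couple[0] == 0) is updated in place, one
    indicator at a time in index order; ``unifs`` supplies the H-1 uniform
    variates.  For each candidate value the marginal likelihood is fully
    re-evaluated because delta_k enters the w~ recursion of all later
    segments.  Returns the suite evaluation of the final state.
    """
    H = starts.shape[0]
    lam = np.empty(H)
    for k in range(1, H):
        lp = np.empty(2)
        for cand in range(2):
            couple[k] = cand
            for h in range(H):
                lam[h] = lam_c if couple[h] == 1 else lam_u
            lam[0] = lam_u
            ml, _, _, _ = suite(y, X, starts, ends, lam, couple, a_sig, b_sig)
            lp[cand] = ml + _log_delta_prior(couple, a, b)
        p1 = 1.0 / (1.0 + math.exp(lp[0] - lp[1]))
        couple[k] = 1 if unifs[k - 1] < p1 else 0
    for h in range(H):
        lam[h] = lam_c if couple[h] == 1 else lam_u
    lam[0] = lam_u
    return suite(y, X, starts, ends, lam, couple, a_sig, b_sig)
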