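"""Numba kernels for the O(T m^2) recursions.

All kernels take per-dive log emission densities ``logf`` (T, m), the
time-varying transition matrices ``Gamma`` (T-1, m, m) and the initial
distribution ``delta``.  The forward recursion is scaled (normalised
forward vector, accumulated log scale factors), which gives the exact
log-likelihood without per-entry log-sum-exp.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_loglik(logf, Gamma, delta):
    T, m = logf.shape
    w = np.empty(m)
    c = logf[0].max()
    for i in range(m):
        w[i] = delta[i] * np.exp(logf[0, i] - c)
    s = w.sum()
    ll = c + np.log(s)
    for i in range(m):
        w[i] /= s
    for t in range(1, T):
        c = logf[t].max()
        v = np.zeros(m)
        for j in range(m):
            acc = 0.0
            for i in range(m):
                acc += w[i] * Gamma[t - 1, i, j]
            v[j] = acc * np.exp(logf[t, j] - c)
        s = v.sum()
        ll += c + np.log(s)
        for j in range(m):
            w[j] = v[j] / s
    return ll


@njit(cache=True)
def forward_backward(logf, Gamma, delta):
    """Scaled forward-backward.

    Returns (loglik, post, xi): ``post[t, i]`` = P(C_t = i | data) and
    ``xi[t, i, j]`` = P(C_t = i, C_{t+1} = j | data).
    """
    T, m = logf.shape
    alpha = np.empty((T, m))
    fstar = np.empty((T, m))
    cmax = np.empty(T)
    ll = 0.0
    for t in range(T):
        cmax[t] = logf[t].max()
        for i in range(m):
            fstar[t, i] = np.exp(logf[t, i] - cmax[t])
    # forward
    s = 0.0
    for i in range(m):
        alpha[0, i] = delta[i] * fstar[0, i]
        s += alpha[0, i]
    ll = cmax[0] + np.log(s)
    for i in range(m):
        alpha[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(m):
            acc = 0.0
            for i in range(m):
                acc += alpha[t - 1, i] * Gamma[t - 1, i, j]
            alpha[t, j] = acc * fstar[t, j]
            s += alpha[t, j]
        ll += cmax[t] + np.log(s)
        for j in range(m):
            alpha[t, j] /= s
    # backward (renormalised each step)
    beta = np.empty((T, m))
    for i in range(m):
        beta[T - 1, i] = 1.0 / m
    post = np.empty((T, m))
    xi = np.zeros((T - 1, m, m))
    s = 0.0
    for i in range(m):
        post[T - 1, i] = alpha[T - 1, i] * beta[T - 1, i]
        s += post[T - 1, i]
    for i in range(m):
        post[T - 1, i] /= s
    for t in range(T - 2, -1, -1):
        s = 0.0
        for i in range(m):
            acc = 0.0
            for j in range(m):
                acc += Gamma[t, i, j] * fstar[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc
            s += acc
        for i in range(m):
            beta[t, i] /= s
        z = 0.0
        for i in range(m):
            for j in range(m):
                v = alpha[t, i] * Gamma[t, i, j] * fstar[t + 1, j] * beta[t + 1, j]
                xi[t, i, j] = v
                z += v
        sp = 0.0
        for i in range(m):
            post[t, i] = alpha[t, i] * beta[t, i]
            sp += post[t, i]
        for i in range(m):
            post[t, i] /= sp
            for j in range(m):
                xi[t, i, j] /= z
    return ll, post, xi


@njit(cache=True)
def predictive_probs(logf, Gamma, delta):
    """One-step-ahead state probabilities P(C_t = i | x_1..x_{t-1}).

    Row 0 is the initial distribution delta.
    """
    T, m = logf.shape
    P = np.empty((T, m))
    w = np.empty(m)
    for i in range(m):
        P[0, i] = delta[i]
    c = logf[0].max()
    s = 0.0
    for i in range(m):
        w[i] = delta[i] * np.exp(logf[0, i] - c)
        s += w[i]
    for i in range(m):
        w[i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(m):
            acc = 0.0
            for i in range(m):
                acc += w[i] * Gamma[t - 1, i, j]
            P[t, j] = acc
        c = logf[t].max()
        for j in range(m):
            w[j] = P[t, j] * np.exp(logf[t, j] - c)
            s += w[j]
        for j in range(m):
            w[j] /= s
    return P


@njit(cache=True)
def viterbi_path(logf, logGamma, logdelta):
    """Most probable state path (0-based); ties break to the lowest index."""
    T, m = logf.shape
    phi = np.empty((T, m))
    back = np.zeros((T, m), dtype=np.int64)
    for i in range(m):
        phi[0, i] = logdelta[i] + logf[0, i]
    for t in range(1, T):
        for j in range(m):
            best = phi[t - 1, 0] + logGamma[t - 1, 0, j]
            arg = 0
            for i in range(1, m):
                v = phi[t - 1, i] + logGamma[t - 1, i, j]
                if v > best:  # strict: ties keep the lowest index
                    best = v
                    arg = i
            phi[t, j] = best + logf[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = phi[T - 1, 0]
    arg = 0
    for i in range(1, m):
        if phi[T - 1, i] > best:
            best = phi[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
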