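"""Scaled forward-backward and Viterbi kernels (numba-compiled).

Per-position scaling keeps the recursions in probability space without
underflow, so results are independent of sequence length up to floating
round-off.
"""

import numba
import numpy as np


@numba.njit(cache=False)
def forward_backward(framelik, startprob, transmat):
    """Returns (loglik, gamma, xi_sum) for one observation sequence.

    framelik : (T, K) per-position observation likelihoods
    gamma    : (T, K) posterior state probabilities
    xi_sum   : (K, K) expected transition counts summed over t
    """
    T, K = framelik.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    scale = np.empty(T)

    for k in range(K):
        alpha[0, k] = startprob[k] * framelik[0, k]
    s = alpha[0].sum()
    if s <= 0.0:
        s = 1e-300
    scale[0] = s
    alpha[0] /= s
    for t in range(1, T):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * transmat[j, k]
            alpha[t, k] = acc * framelik[t, k]
        s = alpha[t].sum()
        if s <= 0.0:
            s = 1e-300
        scale[t] = s
        alpha[t] /= s

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += transmat[k, j] * framelik[t + 1, j] * beta[t + 1, j]
            beta[t, k] = acc / scale[t + 1]

    gamma = alpha * beta
    for t in range(T):
        g = gamma[t].sum()
        if g > 0.0:
            gamma[t] /= g

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        denom = scale[t + 1]
        for j in range(K):
            a = alpha[t, j]
            for k in range(K):
                xi_sum[j, k] += (
                    a * transmat[j, k] * framelik[t + 1, k] * beta[t + 1, k] / denom
                )

    loglik = np.log(scale).sum()
    return loglik, gamma, xi_sum


@numba.njit(cache=False)
def viterbi(logframelik, logstart, logtrans):
    """Most probable state path for one sequence (log-space)."""
    T, K = logframelik.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = logstart + logframelik[0]
    for t in range(1, T):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + logtrans[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logframelik[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = -1e300
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
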