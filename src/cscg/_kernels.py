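"""Numba kernels for block-sparse message passing.

The clone-structured emission lets every forward/backward step touch only the
M_{x_n} x M_{x_{n+1}} block of the transition tensor selected by the observed
symbols and action, so the cost per step scales with the clone count, never the
alphabet size.  Messages are normalized per step and the normalizers accumulated
in log space so 50,000+-step sequences do not underflow.

All kernels take the model as raw arrays: ``T`` (H, n_actions, H), ``pi`` (H,),
``offsets`` (E+1,) clone-block boundaries, ``x`` (N,) observations, ``a`` (N-1,)
actions.  Message arrays are padded to the widest clone block.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def forward(T, pi, offsets, x, a, alphas, scales):
    """Scaled forward pass restricted to clone blocks.

    Fills ``alphas[n, :M_{x_n}]`` (each row sums to 1) and ``scales``; returns
    the log-likelihood, or -inf if the sequence has probability zero.
    """
    N = x.shape[0]
    i0 = offsets[x[0]]
    m = offsets[x[0] + 1] - i0
    s = 0.0
    for i in range(m):
        v = pi[i0 + i]
        alphas[0, i] = v
        s += v
    scales[0] = s
    if s <= 0.0:
        return NEG_INF
    for i in range(m):
        alphas[0, i] /= s
    loglik = np.log(s)
    for n in range(N - 1):
        i0 = offsets[x[n]]
        mi = offsets[x[n] + 1] - i0
        j0 = offsets[x[n + 1]]
        mj = offsets[x[n + 1] + 1] - j0
        k = a[n]
        for j in range(mj):
            alphas[n + 1, j] = 0.0
        for i in range(mi):
            ai = alphas[n, i]
            if ai == 0.0:
                continue
            for j in range(mj):
                alphas[n + 1, j] += ai * T[i0 + i, k, j0 + j]
        s = 0.0
        for j in range(mj):
            s += alphas[n + 1, j]
        scales[n + 1] = s
        if s <= 0.0:
            return NEG_INF
        for j in range(mj):
            alphas[n + 1, j] /= s
        loglik += np.log(s)
    return loglik


@njit(cache=True)
def backward(T, offsets, x, a, scales, betas):
    """Scaled backward pass; ``betas[n]`` is scaled so alpha(n).beta(n) = 1."""
    N = x.shape[0]
    mN = offsets[x[N - 1] + 1] - offsets[x[N - 1]]
    for i in range(mN):
        betas[N - 1, i] = 1.0
    for n in range(N - 2, -1, -1):
        i0 = offsets[x[n]]
        mi = offsets[x[n] + 1] - i0
        j0 = offsets[x[n + 1]]
        mj = offsets[x[n + 1] + 1] - j0
        k = a[n]
        c = scales[n + 1]
        for i in range(mi):
            acc = 0.0
            for j in range(mj):
                acc += T[i0 + i, k, j0 + j] * betas[n + 1, j]
            betas[n, i] = acc / c


@njit(cache=True)
def accumulate_counts(T, offsets, x, a, alphas, betas, scales, counts, prior_counts):
    """Add expected transition counts xi_{ikj}(n) and gamma(1) to accumulators."""
    N = x.shape[0]
    i0 = offsets[x[0]]
    m0 = offsets[x[0] + 1] - i0
    for i in range(m0):
        prior_counts[i0 + i] += alphas[0, i] * betas[0, i]
    for n in range(N - 1):
        i0 = offsets[x[n]]
        mi = offsets[x[n] + 1] - i0
        j0 = offsets[x[n + 1]]
        mj = offsets[x[n + 1] + 1] - j0
        k = a[n]
        c = scales[n + 1]
        for i in range(mi):
            ai = alphas[n, i]
            if ai == 0.0:
                continue
            for j in range(mj):
                counts[i0 + i, k, j0 + j] += ai * T[i0 + i, k, j0 + j] * betas[n + 1, j] / c


@njit(cache=True)
def forward_blocks(blocks, bidx, pi, offsets, x, a, alphas, scales):
    """Forward pass reading contiguous per-bigram transition blocks.

    ``blocks[bidx[n], :mi, :mj]`` holds T(C(x_n), a_n, C(x_{n+1})); packing the
    blocks contiguously keeps the sequential sweep cache-friendly on large
    models.  Semantics identical to :func:`forward`.
    """
    N = x.shape[0]
    i0 = offsets[x[0]]
    m = offsets[x[0] + 1] - i0
    s = 0.0
    for i in range(m):
        v = pi[i0 + i]
        alphas[0, i] = v
        s += v
    scales[0] = s
    if s <= 0.0:
        return NEG_INF
    for i in range(m):
        alphas[0, i] /= s
    loglik = np.log(s)
    for n in range(N - 1):
        mi = offsets[x[n] + 1] - offsets[x[n]]
        mj = offsets[x[n + 1] + 1] - offsets[x[n + 1]]
        B = blocks[bidx[n]]
        for j in range(mj):
            alphas[n + 1, j] = 0.0
        for i in range(mi):
            ai = alphas[n, i]
            if ai == 0.0:
                continue
            for j in range(mj):
                alphas[n + 1, j] += ai * B[i, j]
        s = 0.0
        for j in range(mj):
            s += alphas[n + 1, j]
        scales[n + 1] = s
        if s <= 0.0:
            return NEG_INF
        for j in range(mj):
            alphas[n + 1, j] /= s
        loglik += np.log(s)
    return loglik


@njit(cache=True)
def backward_blocks(blocks, bidx, offsets, x, a, scales, betas):
    """Scaled backward pass over contiguous per-bigram blocks."""
    N = x.shape[0]
    mN = offsets[x[N - 1] + 1] - offsets[x[N - 1]]
    for i in range(mN):
        betas[N - 1, i] = 1.0
    for n in range(N - 2, -1, -1):
        mi = offsets[x[n] + 1] - offsets[x[n]]
        mj = offsets[x[n + 1] + 1] - offsets[x[n + 1]]
        B = blocks[bidx[n]]
        c = scales[n + 1]
        for i in range(mi):
            acc = 0.0
            for j in range(mj):
                acc += B[i, j] * betas[n + 1, j]
            betas[n, i] = acc / c


@njit(cache=True)
def backward_counts(T, offsets, x, a, alphas, scales, counts, prior_counts):
    """Backward sweep fused with xi-count accumulation (one pass, E-step hot path)."""
    N = x.shape[0]
    mmax = 0
    for e in range(offsets.shape[0] - 1):
        w = offsets[e + 1] - offsets[e]
        if w > mmax:
            mmax = w
    beta_next = np.ones(mmax)
    beta_cur = np.ones(mmax)
    for n in range(N - 2, -1, -1):
        i0 = offsets[x[n]]
        mi = offsets[x[n] + 1] - i0
        j0 = offsets[x[n + 1]]
        mj = offsets[x[n + 1] + 1] - j0
        k = a[n]
        c = scales[n + 1]
        for i in range(mi):
            acc = 0.0
            ai = alphas[n, i]
            if ai > 0.0:
                for j in range(mj):
                    tb = T[i0 + i, k, j0 + j] * beta_next[j]
                    acc += tb
                    counts[i0 + i, k, j0 + j] += ai * tb / c
            else:
                for j in range(mj):
                    acc += T[i0 + i, k, j0 + j] * beta_next[j]
            beta_cur[i] = acc / c
        for i in range(mi):
            beta_next[i] = beta_cur[i]
    m0 = offsets[x[0] + 1] - offsets[x[0]]
    for i in range(m0):
        prior_counts[offsets[x[0]] + i] += alphas[0, i] * beta_next[i]


@njit(cache=True)
def viterbi(T, pi, offsets, x, a, path):
    """MAP clone path by max-product; ties broken toward the lowest state index.

    Fills ``path`` with absolute state ids and returns the path log-probability
    (-inf when no positive-probability path exists).
    """
    N = x.shape[0]
    mmax = 0
    for e in range(offsets.shape[0] - 1):
        w = offsets[e + 1] - offsets[e]
        if w > mmax:
            mmax = w
    scores = np.full((N, mmax), NEG_INF)
    back = np.zeros((N, mmax), dtype=np.int64)
    i0 = offsets[x[0]]
    m = offsets[x[0] + 1] - i0
    for i in range(m):
        p = pi[i0 + i]
        scores[0, i] = np.log(p) if p > 0.0 else NEG_INF
    for n in range(N - 1):
        i0 = offsets[x[n]]
        mi = offsets[x[n] + 1] - i0
        j0 = offsets[x[n + 1]]
        mj = offsets[x[n + 1] + 1] - j0
        k = a[n]
        for j in range(mj):
            scores[n + 1, j] = NEG_INF
            back[n + 1, j] = 0
        for i in range(mi):
            si = scores[n, i]
            if si == NEG_INF:
                continue
            for j in range(mj):
                t = T[i0 + i, k, j0 + j]
                if t <= 0.0:
                    continue
                v = si + np.log(t)
                if v > scores[n + 1, j]:
                    scores[n + 1, j] = v
                    back[n + 1, j] = i
    iN = offsets[x[N - 1]]
    mN = offsets[x[N - 1] + 1] - iN
    best = NEG_INF
    arg = 0
    for j in range(mN):
        if scores[N - 1, j] > best:
            best = scores[N - 1, j]
            arg = j
    if best == NEG_INF:
        return NEG_INF
    path[N - 1] = iN + arg
    cur = arg
    for n in range(N - 1, 0, -1):
        cur = back[n, cur]
        path[n - 1] = offsets[x[n - 1]] + cur
    return best


@njit(cache=True)
def count_flops_forward(offsets, x):
    """Multiply-accumulate count of one forward pass (computational contract)."""
    total = 0
    N = x.shape[0]
    for n in range(N - 1):
        mi = offsets[x[n] + 1] - offsets[x[n]]
        mj = offsets[x[n + 1] + 1] - offsets[x[n + 1]]
        total += mi * mj
    return total
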