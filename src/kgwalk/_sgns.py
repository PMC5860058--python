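"""Numba kernel for skip-gram negative-sampling SGD.

Sequential single-worker training: deterministic for a fixed seed.  The
math per (input, output) pair is the negative-sampling objective
log σ(v'_O · v_I) + Σ_k log σ(-v'_i · v_I) ascended by its analytic
gradient (see :func:`kgwalk.embeddings.sgns_objective`, against which the
kernel is checked).
"""
import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(x):
    if x > 30.0:
        return 1.0
    if x < -30.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def train_epochs(flat, offsets, win_in, win_out, keep, cum, context, k,
                 alpha0, min_alpha, epochs, seed):
    """Train in place over the encoded corpus; returns nothing."""
    np.random.seed(seed)
    dim = win_in.shape[1]
    n_tokens = flat.shape[0]
    total = epochs * n_tokens + 1
    processed = 0
    kept = np.empty(n_tokens, dtype=np.int32)
    err = np.empty(dim, dtype=np.float64)
    for _epoch in range(epochs):
        for s in range(offsets.shape[0] - 1):
            n = 0
            for idx in range(offsets[s], offsets[s + 1]):
                w = flat[idx]
                processed += 1
                if keep[w] >= 1.0 or np.random.random() < keep[w]:
                    kept[n] = w
                    n += 1
            for i in range(n):
                alpha = alpha0 * (1.0 - processed / total)
                if alpha < min_alpha:
                    alpha = min_alpha
                wi = kept[i]
                reduced = np.random.randint(0, context)
                window = context - reduced
                lo = i - window
                if lo < 0:
                    lo = 0
                hi = i + window + 1
                if hi > n:
                    hi = n
                for j in range(lo, hi):
                    if j == i:
                        continue
                    wo = kept[j]
                    for d in range(dim):
                        err[d] = 0.0
                    # positive target
                    f = 0.0
                    for d in range(dim):
                        f += win_out[wo, d] * win_in[wi, d]
                    g = (1.0 - _sigmoid(f)) * alpha
                    for d in range(dim):
                        err[d] += g * win_out[wo, d]
                        win_out[wo, d] += g * win_in[wi, d]
                    # k noise draws from the unigram^0.75 table,
                    # redrawn when they hit the input token
                    for _t in range(k):
                        neg = wi
                        for _retry in range(8):
                            r = np.random.random()
                            neg = np.searchsorted(cum, r)
                            if neg >= cum.shape[0]:
                                neg = cum.shape[0] - 1
                            if neg != wi:
                                break
                        if neg == wi:
                            continue
                        f = 0.0
                        for d in range(dim):
                            f += win_out[neg, d] * win_in[wi, d]
                        g = (0.0 - _sigmoid(f)) * alpha
                        for d in range(dim):
                            err[d] += g * win_out[neg, d]
                            win_out[neg, d] += g * win_in[wi, d]
                    for d in range(dim):
                        win_in[wi, d] += err[d]
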