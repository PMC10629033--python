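"""Numba kernel for skip-gram with negative sampling over walk corpora.

Single-threaded by construction so that a fixed seed reproduces the
embedding matrix bit-for-bit.  Gradients follow the classic word2vec SGNS
update: for every (center, context) pair within the window, one positive
update against the context's output vector and ``negative`` updates
against draws from the unigram^0.75 noise distribution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgns_train"]

_MAX_EXP = 6.0


@njit(cache=True, fastmath=False)
def sgns_train(
    tokens: np.ndarray,        # int32 token ids, all sentences concatenated
    offsets: np.ndarray,       # int64 sentence boundaries, len = n_sent + 1
    W: np.ndarray,             # (V, N) input vectors, updated in place
    C: np.ndarray,             # (V, N) output vectors, updated in place
    window: int,
    negative: int,
    noise_cdf: np.ndarray,     # cumulative unigram^0.75 distribution
    alpha0: float,
    min_alpha: float,
    epochs: int,
    seed: int,
) -> None:
    np.random.seed(seed)
    n_tokens = tokens.shape[0]
    dim = W.shape[1]
    total = epochs * n_tokens
    done = 0
    neu1e = np.zeros(dim)
    for _ in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                lr = alpha0 - (alpha0 - min_alpha) * (done / total)
                done += 1
                center = tokens[i]
                lo = i - window
                if lo < start:
                    lo = start
                hi = i + window + 1
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = tokens[j]
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = ctx
                            label = 1.0
                        else:
                            r = np.random.random()
                            target = np.searchsorted(noise_cdf, r)
                            if target == ctx:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += W[center, d] * C[target, d]
                        if dot > _MAX_EXP:
                            fx = 1.0
                        elif dot < -_MAX_EXP:
                            fx = 0.0
                        else:
                            fx = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - fx) * lr
                        for d in range(dim):
                            neu1e[d] += g * C[target, d]
                            C[target, d] += g * W[center, d]
                    for d in range(dim):
                        W[center, d] += neu1e[d]
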