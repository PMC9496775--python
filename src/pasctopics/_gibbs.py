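"""Numba kernel for the collapsed Gibbs sweep.

The sampler state is the token-level topic assignment vector ``z`` plus the
three count arrays derived from it.  One call performs a full sweep over all
tokens in corpus order; the uniform variates are drawn by the caller from a
seeded numpy Generator so the whole chain is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep(
    words: np.ndarray,      # (T,) int32 token word indices, corpus order
    docs: np.ndarray,       # (T,) int32 document index per token
    z: np.ndarray,          # (T,) int32 current topic assignments, mutated
    n_dt: np.ndarray,       # (D, k) int64 doc-topic counts, mutated
    n_tw: np.ndarray,       # (k, V) int64 topic-word counts, mutated
    n_t: np.ndarray,        # (k,) int64 topic totals, mutated
    alpha: float,
    eta: float,
    uniforms: np.ndarray,   # (T,) float64 in [0, 1), one per token
    cum: np.ndarray,        # (k,) float64 scratch
) -> None:
    k = n_t.shape[0]
    V = n_tw.shape[1]
    Veta = V * eta
    for i in range(words.shape[0]):
        w = words[i]
        d = docs[i]
        t_old = z[i]
        n_dt[d, t_old] -= 1
        n_tw[t_old, w] -= 1
        n_t[t_old] -= 1
        total = 0.0
        for t in range(k):
            p = (n_dt[d, t] + alpha) * (n_tw[t, w] + eta) / (n_t[t] + Veta)
            total += p
            cum[t] = total
        u = uniforms[i] * total
        t_new = 0
        while cum[t_new] < u and t_new < k - 1:
            t_new += 1
        z[i] = t_new
        n_dt[d, t_new] += 1
        n_tw[t_new, w] += 1
        n_t[t_new] += 1
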