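"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the collapsed LDA
posterior is computed by exhaustive enumeration of assignment vectors, and
MST minimality is certified by scanning all edge subsets.
"""

from __future__ import annotations

import itertools
from math import lgamma

import numpy as np


def collapsed_log_joint(z, words, alpha, eta, k, V) -> float:
    """log p(z, w) of LDA for one document with theta and phi integrated out."""
    n_dt = np.zeros(k)
    n_tw = np.zeros((k, V))
    for zi, wi in zip(z, words):
        n_dt[zi] += 1
        n_tw[zi, wi] += 1
    lp = sum(lgamma(n_dt[t] + alpha) - lgamma(alpha) for t in range(k))
    for t in range(k):
        lp += lgamma(V * eta) - lgamma(n_tw[t].sum() + V * eta)
        lp += sum(lgamma(n_tw[t, w] + eta) - lgamma(eta) for w in range(V))
    return lp


def enumerate_assignment_posterior(words, alpha, eta, k, V) -> dict[tuple, float]:
    """Exact posterior over all k^N topic-assignment vectors of one document."""
    zs = list(itertools.product(range(k), repeat=len(words)))
    lps = np.array([collapsed_log_joint(z, words, alpha, eta, k, V) for z in zs])
    post = np.exp(lps - lps.max())
    post /= post.sum()
    return dict(zip(zs, post))


def batch_means_se(indicator: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of a chain mean from batch means (correlation-robust)."""
    usable = len(indicator) - len(indicator) % n_batches
    batches = indicator[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def brute_force_mst_weight(W: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive search.

    All (n-1)-edge subsets are scanned in ascending total weight; the first
    connected one is the global minimum spanning tree.
    """
    n = W.shape[0]
    iu, ju = np.triu_indices(n, 1)
    weights = W[iu, ju]
    m = len(weights)
    combos = np.fromiter(
        (i for c in itertools.combinations(range(m), n - 1) for i in c),
        dtype=np.int64,
    ).reshape(-1, n - 1)
    order = np.argsort(weights[combos].sum(axis=1), kind="stable")

    def spans(edge_idx) -> bool:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged = 0
        for e in edge_idx:
            ru, rv = find(int(iu[e])), find(int(ju[e]))
            if ru != rv:
                parent[ru] = rv
                merged += 1
        return merged == n - 1

    for row in order:
        if spans(combos[row]):
            return float(weights[combos[row]].sum())
    raise AssertionError("no spanning subset found")
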