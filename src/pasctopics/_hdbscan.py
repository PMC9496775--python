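"""Hierarchical density-based clustering (HDBSCAN) from first principles.

Pipeline: core distances -> mutual reachability graph -> minimum spanning
tree (Prim) -> single-linkage dendrogram -> condensed tree (pruning
components smaller than ``min_cluster_size``) -> excess-of-mass cluster
selection -> flat labels with -1 for noise.

Densities are expressed as lambda = 1 / distance; a point "falls out" of a
cluster at the lambda where its mutual-reachability link breaks, and a
cluster's stability is the total lambda-mass its points accumulate between
the cluster's birth and their fall-out.  Selected clusters maximize summed
stability over every antichain of the condensed tree (the excess-of-mass
rule), with the dendrogram root never eligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

# lambda substituted for 1/0 when two points coincide
_INF_LAMBDA = 1e12


def pairwise_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    D = cdist(X, X, metric=metric)
    np.fill_diagonal(D, 0.0)
    return D


def core_distances(D: np.ndarray, min_samples: int) -> np.ndarray:
    """Distance to each point's ``min_samples``-th nearest neighbor.

    The point itself counts as its own first neighbor (distance 0), the
    convention of the reference implementations.
    """
    n = D.shape[0]
    k = min(min_samples, n)
    return np.sort(D, axis=1)[:, k - 1]


def mutual_reachability(D: np.ndarray, core: np.ndarray) -> np.ndarray:
    """d_mreach(a, b) = max(core(a), core(b), d(a, b)); 0 on the diagonal."""
    M = np.maximum(D, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(M, 0.0)
    return M


def mst_edges(W: np.ndarray) -> np.ndarray:
    """Minimum spanning tree of a dense symmetric weight matrix (Prim).

    Returns an (n-1, 3) array of (u, v, weight) rows in insertion order.
    """
    n = W.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = W[0].copy()
    best[0] = np.inf
    parent = np.zeros(n, dtype=np.int64)
    edges = np.empty((n - 1, 3), dtype=np.float64)
    for e in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        edges[e] = (parent[j], j, best[j])
        in_tree[j] = True
        best[j] = np.inf
        improved = ~in_tree & (W[j] < best)
        parent[improved] = j
        best[improved] = W[j][improved]
    return edges


def single_linkage(edges: np.ndarray, n: int) -> np.ndarray:
    """Union-find agglomeration of MST edges sorted by ascending weight.

    Returns a scipy-style linkage array: row i merges nodes
    (Z[i,0], Z[i,1]) at distance Z[i,2] into node ``n + i`` of size Z[i,3].
    """
    order = np.argsort(edges[:, 2], kind="stable")
    parent = np.arange(2 * n - 1, dtype=np.int64)
    current = np.arange(n, dtype=np.int64)  # point -> current dendrogram node
    size = np.ones(2 * n - 1, dtype=np.int64)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    Z = np.empty((n - 1, 4), dtype=np.float64)
    nxt = n
    for i, e in enumerate(order):
        u, v, w = int(edges[e, 0]), int(edges[e, 1]), edges[e, 2]
        ru, rv = find(u), find(v)
        a, b = current[ru], current[rv]
        Z[i] = (a, b, w, size[a] + size[b])
        size[nxt] = size[a] + size[b]
        parent[ru] = rv
        root = find(rv)
        current[root] = nxt
        nxt += 1
    return Z


@dataclass
class CondensedTree:
    """Pruned cluster hierarchy.

    Rows are (parent, child, lambda_val, child_size); children of size 1
    are points falling out of their parent cluster, larger children are
    true sub-clusters.  Cluster ids start at ``n`` (the root).
    """

    parent: np.ndarray
    child: np.ndarray
    lambda_val: np.ndarray
    child_size: np.ndarray
    n_points: int


def _dendrogram_leaves(Z: np.ndarray, node: int, n: int) -> list[int]:
    out: list[int] = []
    stack = [node]
    while stack:
        x = stack.pop()
        if x < n:
            out.append(x)
        else:
            row = Z[x - n]
            stack.append(int(row[0]))
            stack.append(int(row[1]))
    return out


def condense_tree(Z: np.ndarray, min_cluster_size: int) -> CondensedTree:
    """Prune the single-linkage dendrogram into the condensed cluster tree."""
    n = Z.shape[0] + 1
    root = 2 * n - 2
    relabel = {root: n}
    next_label = n + 1
    rows: list[tuple[int, int, float, int]] = []
    visited: set[int] = set()

    # walk internal nodes top-down, highest merge (largest distance) first
    for node in range(root, n - 1, -1):
        if node in visited:
            continue
        cluster = relabel.get(node)
        if cluster is None:  # subtree already dissolved into its parent
            continue
        left, right, dist, _ = Z[node - n]
        left, right = int(left), int(right)
        lam = 1.0 / dist if dist > 0 else _INF_LAMBDA
        l_size = 1 if left < n else int(Z[left - n, 3])
        r_size = 1 if right < n else int(Z[right - n, 3])

        if l_size >= min_cluster_size and r_size >= min_cluster_size:
            # true split: both sides persist as new condensed clusters
            for ch, sz in ((left, l_size), (right, r_size)):
                relabel[ch] = next_label
                rows.append((cluster, next_label, lam, sz))
                next_label += 1
        elif l_size < min_cluster_size and r_size < min_cluster_size:
            # the cluster dissolves entirely at this density
            for ch in (left, right):
                for p in _dendrogram_leaves(Z, ch, n):
                    rows.append((cluster, p, lam, 1))
                if ch >= n:
                    visited.update(_dendrogram_subnodes(Z, ch, n))
        else:
            # spurious split: the small side falls out point by point and
            # the big side continues as the same condensed cluster
            big, small = (left, right) if l_size >= r_size else (right, left)
            relabel[big] = cluster
            for p in _dendrogram_leaves(Z, small, n):
                rows.append((cluster, p, lam, 1))
            if small >= n:
                visited.update(_dendrogram_subnodes(Z, small, n))

    arr = np.asarray(rows, dtype=np.float64).reshape(-1, 4)
    return CondensedTree(
        parent=arr[:, 0].astype(np.int64),
        child=arr[:, 1].astype(np.int64),
        lambda_val=arr[:, 2],
        child_size=arr[:, 3].astype(np.int64),
        n_points=n,
    )


def _dendrogram_subnodes(Z: np.ndarray, node: int, n: int) -> list[int]:
    out: list[int] = []
    stack = [node]
    while stack:
        x = stack.pop()
        if x >= n:
            out.append(x)
            row = Z[x - n]
            stack.append(int(row[0]))
            stack.append(int(row[1]))
    return out


def cluster_stability(tree: CondensedTree) -> dict[int, float]:
    """stability(c) = sum over departures (lambda_leave - lambda_birth) * size."""
    births: dict[int, float] = {tree.n_points: 0.0}
    for p, c, lam, sz in zip(tree.parent, tree.child, tree.lambda_val, tree.child_size):
        if sz > 1:
            births[int(c)] = lam
    stability: dict[int, float] = {c: 0.0 for c in births}
    for p, c, lam, sz in zip(tree.parent, tree.child, tree.lambda_val, tree.child_size):
        stability[int(p)] += (lam - births[int(p)]) * int(sz)
    return stability


def select_clusters_eom(tree: CondensedTree) -> set[int]:
    """Excess-of-mass selection over the condensed cluster tree.

    Bottom-up: a cluster is kept if its own stability exceeds (>=) the sum
    of its children's propagated stabilities; the root is never selected.
    """
    stability = cluster_stability(tree)
    cluster_rows = tree.child_size > 1
    children: dict[int, list[int]] = {c: [] for c in stability}
    for p, c in zip(tree.parent[cluster_rows], tree.child[cluster_rows]):
        children[int(p)].append(int(c))

    root = tree.n_points
    is_cluster = {c: True for c in stability}
    for node in sorted(stability, reverse=True):
        if node == root:
            continue
        subtree = sum(stability[ch] for ch in children[node])
        if children[node] and subtree > stability[node]:
            stability[node] = subtree
            is_cluster[node] = False
        else:
            # select this node, deselect every descendant cluster
            stack = list(children[node])
            while stack:
                d = stack.pop()
                is_cluster[d] = False
                stack.extend(children[d])
    is_cluster[root] = False
    return {c for c, keep in is_cluster.items() if keep}


def labels_and_probabilities(
    tree: CondensedTree, selected: set[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flat labels (selected-cluster id or -1) and soft membership strengths."""
    n = tree.n_points
    cluster_parent: dict[int, int] = {}
    for p, c, sz in zip(tree.parent, tree.child, tree.child_size):
        if sz > 1:
            cluster_parent[int(c)] = int(p)

    point_cluster = np.full(n, -1, dtype=np.int64)
    point_lambda = np.zeros(n, dtype=np.float64)
    for p, c, lam, sz in zip(tree.parent, tree.child, tree.lambda_val, tree.child_size):
        if sz == 1:
            point_cluster[int(c)] = int(p)
            point_lambda[int(c)] = lam

    def owning(c: int) -> int:
        while c != -1:
            if c in selected:
                return c
            c = cluster_parent.get(c, -1)
        return -1

    labels = np.array([owning(int(c)) for c in point_cluster], dtype=np.int64)

    # per selected cluster, the densest departure bounds the strengths
    probs = np.zeros(n, dtype=np.float64)
    for c in selected:
        mask = labels == c
        if not mask.any():
            continue
        lam_max = point_lambda[mask].max()
        if lam_max <= 0:
            probs[mask] = 1.0
        else:
            probs[mask] = np.minimum(point_lambda[mask], lam_max) / lam_max
    return labels, probs


def hdbscan_flat(
    X: np.ndarray,
    min_cluster_size: int = 10,
    min_samples: int | None = None,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Full HDBSCAN run returning (labels, strengths).

    Labels are renumbered 1..C by decreasing cluster size (ties: cluster
    containing the lowest point index first); noise is -1.  If there are
    fewer points than ``min_cluster_size`` everything is noise.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if min_samples is None:
        min_samples = min_cluster_size
    if n < min_cluster_size:
        warnings.warn(
            f"{n} points < min_cluster_size={min_cluster_size}: all points noise",
            UserWarning,
            stacklevel=2,
        )
        return np.full(n, -1, dtype=np.int64), np.zeros(n)

    D = pairwise_distances(X, metric)
    core = core_distances(D, min_samples)
    M = mutual_reachability(D, core)
    Z = single_linkage(mst_edges(M), n)
    tree = condense_tree(Z, min_cluster_size)
    selected = select_clusters_eom(tree)
    raw_labels, probs = labels_and_probabilities(tree, selected)

    # renumber by decreasing size, 1-based, noise stays -1
    labels = np.full(n, -1, dtype=np.int64)
    uniq = [c for c in np.unique(raw_labels) if c != -1]
    order = sorted(
        uniq,
        key=lambda c: (-(raw_labels == c).sum(), int(np.flatnonzero(raw_labels == c)[0])),
    )
    for new, c in enumerate(order, start=1):
        labels[raw_labels == c] = new
    return labels, probs
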