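"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately avoid the implementation's spatial indexes and library
clustering: all-pairs distance evaluation and a textbook DBSCAN written from
its definition.
"""

from __future__ import annotations

import numpy as np


def brute_force_coincident_flags(
    pos_a: np.ndarray, prec_a: np.ndarray, pos_b: np.ndarray, prec_b: np.ndarray
) -> np.ndarray:
    """All-pairs evaluation of dist(a, b) <= prec_a + prec_b per A record."""
    flags = np.zeros(len(pos_a), dtype=bool)
    for i in range(len(pos_a)):
        for j in range(len(pos_b)):
            d = np.hypot(pos_a[i, 0] - pos_b[j, 0], pos_a[i, 1] - pos_b[j, 1])
            if d <= prec_a[i] + prec_b[j]:
                flags[i] = True
                break
    return flags


def brute_force_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """O(n^2) DBSCAN from the definition: labels, -1 for noise.

    Core point: >= min_samples neighbours within eps (self included).
    Clusters are the connected components of core points under eps-adjacency;
    border points join the cluster of any core neighbour.
    """
    n = len(points)
    d = np.hypot(
        points[:, None, 0] - points[None, :, 0],
        points[:, None, 1] - points[None, :, 1],
    )
    adj = d <= eps
    core = adj.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # flood fill over core connectivity
        stack = [i]
        labels[i] = cluster
        while stack:
            k = stack.pop()
            if not core[k]:
                continue
            for j in np.flatnonzero(adj[k]):
                if labels[j] == -1:
                    labels[j] = cluster
                    if core[j]:
                        stack.append(j)
        cluster += 1
    return labels


def canonical_partition(labels: np.ndarray) -> list[frozenset]:
    """Cluster memberships as an order-independent set of frozensets."""
    out = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        out.append(frozenset(np.flatnonzero(labels == lab).tolist()))
    return sorted(out, key=min)
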