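"""Independent brute-force oracles used by the network tests.

Deliberately avoid the implementation's code paths: connectivity comes
from scipy.sparse.csgraph instead of networkx, and partition density is
re-derived from first principles.
"""

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def percolation_scan(A: np.ndarray) -> float | None:
    """Exhaustive threshold scan replicating the spanning-giant rule.

    Returns the largest unique weight t at which the >=t subgraph keeps all
    non-isolated nodes in one component; falls back to the candidate
    maximizing (giant size - isolated count), preferring larger t on ties.
    Returns None for an all-zero adjacency.
    """
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    w = A[iu]
    pos = w > 0
    if not pos.any():
        return None
    active = np.unique(np.concatenate([iu[0][pos], iu[1][pos]]))
    spanning = []
    scored = []
    for t in np.unique(w[pos]):
        mask = pos & (w >= t)
        m = np.zeros((n, n))
        m[iu[0][mask], iu[1][mask]] = 1
        m = m + m.T
        sub = m[np.ix_(active, active)]
        n_comp, labels = connected_components(csr_matrix(sub), directed=False)
        sizes = np.bincount(labels)
        giant = sizes.max()
        isolated = int((sizes == 1).sum())
        if giant == len(active):
            spanning.append(t)
        scored.append((giant - isolated, t))
    if spanning:
        return float(max(spanning))
    best = max(scored, key=lambda s: (s[0], s[1]))
    return float(best[1])


def partition_density(labels, edges) -> float:
    """ABL partition density, re-derived: D = (2/M) sum_c m_c (m_c-n_c+1) /
    ((n_c-2)(n_c-1)), communities with n_c <= 2 contributing zero."""
    m = len(edges)
    acc = 0.0
    for lab in set(labels):
        idx = [e for e, l in enumerate(labels) if l == lab]
        mc = len(idx)
        nodes = set()
        for e in idx:
            nodes.add(edges[e][0])
            nodes.add(edges[e][1])
        nc = len(nodes)
        if nc > 2:
            acc += mc * (mc - nc + 1) / ((nc - 2) * (nc - 1))
    return 2.0 * acc / m


def random_graph_adjacency(n: int, rng, p_edge: float = 0.6) -> np.ndarray:
    """Random weighted adjacency with distinct positive weights."""
    A = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    keep = rng.random(len(iu[0])) < p_edge
    weights = rng.permutation(len(iu[0]))[: keep.sum()] + 1.0
    A[iu[0][keep], iu[1][keep]] = weights / len(iu[0])
    return A + A.T
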