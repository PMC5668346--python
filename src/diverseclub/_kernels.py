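"""Compiled graph kernels (numba) used by the null models and the generative model.

Everything here works on a CSR-like adjacency (indptr/indices) built from the
binary topology. The expensive inner loop of the generative model — the change
in the all-pairs shortest-path sum when each single edge is removed — uses an
exact incremental scheme: all-pairs distances and shortest-path counts are
computed once, and a source ``i`` needs re-exploration after deleting edge
(u, v) only if *every* shortest path from ``i`` to the far endpoint crosses
that edge, i.e. ``d(i,u) + 1 == d(i,v)`` and ``sigma(i,u) == sigma(i,v)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "build_csr",
    "pathsum",
    "bfs_all",
    "delta_pathsums",
    "double_edge_swap_kernel",
]


def build_csr(n: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency in CSR form (indptr, indices) from an (m, 2) edge array."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    indptr = np.zeros(n + 1, np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return indptr, indices


@njit(cache=True)
def pathsum(n, indptr, indices):
    """Sum of binary shortest-path lengths over unordered pairs; -1 if disconnected."""
    total = 0
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for src in range(n):
        for j in range(n):
            dist[j] = -1
        dist[src] = 0
        queue[0] = src
        head, tail, seen, acc = 0, 1, 1, 0
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            acc += du
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
                    seen += 1
        if seen < n:
            return -1
        total += acc
    return total // 2


@njit(cache=True)
def bfs_all(n, indptr, indices):
    """All-pairs BFS distances and shortest-path counts."""
    D = np.full((n, n), -1, np.int32)
    S = np.zeros((n, n), np.float64)
    queue = np.empty(n, np.int32)
    for src in range(n):
        D[src, src] = 0
        S[src, src] = 1.0
        queue[0] = src
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = D[src, u]
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if D[src, v] < 0:
                    D[src, v] = du + 1
                    queue[tail] = v
                    tail += 1
                    S[src, v] = S[src, u]
                elif D[src, v] == du + 1:
                    S[src, v] += S[src, u]
    return D, S


@njit(cache=True)
def delta_pathsums(n, indptr, indices, edges, D, S, is_bridge):
    """Per-edge increase of the all-pairs path sum when that edge is removed.

    ``-1`` marks bridges (removal disconnects; the increase is undefined).
    ``indices`` is modified in place during the call and restored before
    returning.
    """
    m = len(edges)
    out = np.zeros(m, np.int64)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    rowsum = np.empty(n, np.int64)
    for i in range(n):
        s = 0
        for j in range(n):
            s += D[i, j]
        rowsum[i] = s
    for ei in range(m):
        if is_bridge[ei]:
            out[ei] = -1
            continue
        u = edges[ei, 0]
        v = edges[ei, 1]
        ku = -1
        kv = -1
        for k in range(indptr[u], indptr[u + 1]):
            if indices[k] == v:
                ku = k
                break
        for k in range(indptr[v], indptr[v + 1]):
            if indices[k] == u:
                kv = k
                break
        # mask the edge: u's slot for v points back at u (already visited)
        indices[ku] = u
        indices[kv] = v
        delta2 = 0
        for src in range(n):
            affected = False
            if D[src, u] + 1 == D[src, v] and S[src, u] == S[src, v]:
                affected = True
            elif D[src, v] + 1 == D[src, u] and S[src, v] == S[src, u]:
                affected = True
            if not affected:
                continue
            for j in range(n):
                dist[j] = -1
            dist[src] = 0
            queue[0] = src
            head, tail, acc = 0, 1, 0
            while head < tail:
                a = queue[head]
                head += 1
                da = dist[a]
                acc += da
                for k in range(indptr[a], indptr[a + 1]):
                    b = indices[k]
                    if dist[b] < 0:
                        dist[b] = da + 1
                        queue[tail] = b
                        tail += 1
            delta2 += acc - rowsum[src]
        indices[ku] = v
        indices[kv] = u
        out[ei] = delta2 // 2
    return out


@njit(cache=True)
def double_edge_swap_kernel(edges, adj, e1s, e2s, orient):
    """In-place degree-preserving double edge swaps; returns success count.

    Proposals creating self-loops or duplicate edges are rejected and the
    attempt is simply consumed.
    """
    successes = 0
    for t in range(len(e1s)):
        i = e1s[t]
        j = e2s[t]
        if i == j:
            continue
        a, b = edges[i, 0], edges[i, 1]
        c, d = edges[j, 0], edges[j, 1]
        if orient[t]:
            x1, y1, x2, y2 = a, d, c, b
        else:
            x1, y1, x2, y2 = a, c, b, d
        if x1 == y1 or x2 == y2:
            continue
        if (x1 == x2 and y1 == y2) or (x1 == y2 and y1 == x2):
            continue
        if adj[x1, y1] or adj[x2, y2]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[x1, y1] = adj[y1, x1] = True
        adj[x2, y2] = adj[y2, x2] = True
        if x1 < y1:
            edges[i, 0], edges[i, 1] = x1, y1
        else:
            edges[i, 0], edges[i, 1] = y1, x1
        if x2 < y2:
            edges[j, 0], edges[j, 1] = x2, y2
        else:
            edges[j, 0], edges[j, 1] = y2, x2
        successes += 1
    return successes
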