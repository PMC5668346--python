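"""Graph data model, file I/O, cost thresholding, and degree-preserving nulls.

The central object is :class:`WeightedGraph`, an immutable undirected graph
with strictly positive edge weights (1.0 throughout for binary graphs). It is
the substrate of every club computation: the adjacency matrix A_ij, node count
n and edge count m live here. Randomized null graphs — same degree sequence,
edges randomly placed via double edge swaps, optionally with degree-matched
weight shuffling — are produced by :func:`randomize`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import igraph as ig
import numpy as np
import pandas as pd

__all__ = [
    "WeightedGraph",
    "NullEnsemble",
    "load_graph",
    "save_graph",
    "threshold_graph",
    "randomize",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be interpreted in its declared format."""


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph with labeled nodes and positive edge weights.

    Parameters
    ----------
    nodes
        Ordered, unique node labels.
    edges
        ``(m, 2)`` integer array of node indices with ``edges[:, 0] < edges[:, 1]``.
    weights
        ``(m,)`` strictly positive edge weights; all 1.0 for binary graphs.
    """

    nodes: tuple
    edges: np.ndarray
    weights: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(nodes) < 2:
            raise ValueError("a graph needs at least 2 nodes")
        if len(set(nodes)) != len(nodes):
            raise ValueError("node labels must be unique")
        if len(edges) != len(weights):
            raise ValueError("edges and weights length mismatch")
        if len(edges):
            lo = np.minimum(edges[:, 0], edges[:, 1])
            hi = np.maximum(edges[:, 0], edges[:, 1])
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            if lo.min() < 0 or hi.max() >= len(nodes):
                raise ValueError("edge index out of range")
            order = np.lexsort((hi, lo))
            edges = np.column_stack([lo, hi])[order]
            weights = weights[order]
            keys = edges[:, 0] * len(nodes) + edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate edges are not allowed")
            if np.any(weights <= 0):
                raise ValueError("edge weights must be strictly positive")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "weights", weights)

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return self.m / (self.n * (self.n - 1) / 2)

    @property
    def is_binary(self) -> bool:
        return bool(np.all(self.weights == 1.0))

    def index_of(self, node) -> int:
        lookup = self._cache.get("index")
        if lookup is None:
            lookup = {lab: i for i, lab in enumerate(self.nodes)}
            self._cache["index"] = lookup
        try:
            return lookup[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def degree(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n).astype(np.int64)

    def strength(self) -> np.ndarray:
        k = np.zeros(self.n)
        np.add.at(k, self.edges[:, 0], self.weights)
        np.add.at(k, self.edges[:, 1], self.weights)
        return k

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency matrix A with zero diagonal."""
        a = np.zeros((self.n, self.n))
        a[self.edges[:, 0], self.edges[:, 1]] = self.weights
        a[self.edges[:, 1], self.edges[:, 0]] = self.weights
        return a

    def to_igraph(self, weighted: bool = True) -> ig.Graph:
        g = ig.Graph(n=self.n, edges=[tuple(e) for e in self.edges])
        g.vs["name"] = [str(x) for x in self.nodes]
        if weighted:
            g.es["weight"] = list(self.weights)
        return g

    def binarized(self) -> "WeightedGraph":
        return WeightedGraph(self.nodes, self.edges, np.ones(self.m))

    def is_connected(self) -> bool:
        key = "connected"
        if key not in self._cache:
            self._cache[key] = self.to_igraph(weighted=False).is_connected()
        return self._cache[key]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edge_list(cls, pairs: Iterable, weights=None) -> "WeightedGraph":
        """Build from an iterable of (u, v) label pairs plus optional weights."""
        pairs = list(pairs)
        nodes: list = []
        seen = set()
        for u, v in pairs:
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    nodes.append(x)
        idx = {lab: i for i, lab in enumerate(nodes)}
        edges = np.array([[idx[u], idx[v]] for u, v in pairs], dtype=np.int64)
        if weights is None:
            weights = np.ones(len(pairs))
        return cls(tuple(nodes), edges, np.asarray(weights, dtype=float))

    @classmethod
    def from_adjacency(cls, a: np.ndarray, nodes=None) -> "WeightedGraph":
        a = np.asarray(a, dtype=float)
        n = a.shape[0]
        if nodes is None:
            nodes = tuple(str(i) for i in range(n))
        iu, ju = np.triu_indices(n, k=1)
        mask = a[iu, ju] != 0
        return cls(tuple(nodes), np.column_stack([iu[mask], ju[mask]]), a[iu, ju][mask])


@dataclass
class NullEnsemble:
    """A family of degree-preserving randomizations of one source graph."""

    source: WeightedGraph
    graphs: list
    mode: str
    seed: int

    @property
    def size(self) -> int:
        return len(self.graphs)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SUFFIX_FORMAT = {
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".edgelist": "edgelist",
    ".csv": "matrix",
    ".graphml": "graphml",
}


def load_graph(path, format: str | None = None, negative_policy: str = "drop") -> WeightedGraph:
    """Read an undirected graph from an edge-list TSV, square CSV matrix or GraphML.

    Negative edge weights (e.g. negative correlations in functional networks)
    are dropped or rejected according to ``negative_policy`` ("drop" | "error").
    Matrix input must be symmetric within 1e-8; the diagonal is ignored.
    """
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMAT.get(path.suffix.lower())
        if format is None:
            raise GraphFormatError(f"cannot infer format from suffix {path.suffix!r}")
    if negative_policy not in ("drop", "error"):
        raise ValueError("negative_policy must be 'drop' or 'error'")

    if format == "edgelist":
        return _load_edgelist(path, negative_policy)
    if format == "matrix":
        return _load_matrix(path, negative_policy)
    if format == "graphml":
        return _load_graphml(path, negative_policy)
    raise GraphFormatError(f"unknown format {format!r}")


def _apply_negative_policy(pairs, weights, negative_policy):
    weights = np.asarray(weights, dtype=float)
    neg = weights < 0
    if neg.any():
        if negative_policy == "error":
            raise ValueError(f"{int(neg.sum())} negative edge weight(s) present")
        pairs = [p for p, bad in zip(pairs, neg) if not bad]
        weights = weights[~neg]
    return pairs, weights


def _load_edgelist(path, negative_policy) -> WeightedGraph:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GraphFormatError(f"cannot parse edge list {path}: {exc}") from exc
    if df.shape[1] not in (2, 3):
        raise GraphFormatError("edge list must have 2 or 3 tab-separated columns")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first[:2] == ["node_a", "node_b"]:
        df = df.iloc[1:]
    if df.empty:
        raise GraphFormatError("edge list contains no edges")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if df.shape[1] == 3:
        try:
            weights = df.iloc[:, 2].astype(float).to_numpy()
        except ValueError as exc:
            raise GraphFormatError(f"non-numeric weight column: {exc}") from exc
    else:
        weights = np.ones(len(pairs))
    canon = {}
    for (u, v), w in zip(pairs, weights):
        key = (u, v) if u <= v else (v, u)
        if key in canon:
            raise ValueError(f"duplicate edge {key} in {path}")
        canon[key] = w
    pairs, weights = _apply_negative_policy(pairs, weights, negative_policy)
    if np.any(weights == 0):
        pairs = [p for p, w in zip(pairs, weights) if w != 0]
        weights = weights[weights != 0]
    return WeightedGraph.from_edge_list(pairs, weights)


def _load_matrix(path, negative_policy) -> WeightedGraph:
    raw = pd.read_csv(path, header=None, dtype=str)
    labels = None
    # optional header row/column of labels
    body = raw
    try:
        body.astype(float)
    except ValueError:
        labels = [str(x) for x in raw.iloc[0, 1:]]
        body = raw.iloc[1:, 1:]
        try:
            body = body.astype(float)
        except ValueError as exc:
            raise GraphFormatError(f"non-numeric matrix entries in {path}: {exc}") from exc
    a = body.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise GraphFormatError(f"matrix is {a.shape[0]}x{a.shape[1]}, not square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise GraphFormatError("matrix is not symmetric within 1e-8")
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    if negative_policy == "error" and np.any(a < 0):
        raise ValueError("negative weight with policy='error'")
    a[a < 0] = 0.0
    if labels is None:
        labels = tuple(str(i) for i in range(a.shape[0]))
    if a.shape[0] < 2:
        raise ValueError("a graph needs at least 2 nodes")
    return WeightedGraph.from_adjacency(a, tuple(labels))


def _load_graphml(path, negative_policy) -> WeightedGraph:
    try:
        g = ig.Graph.Read_GraphML(str(path))
    except Exception as exc:
        raise GraphFormatError(f"cannot parse GraphML {path}: {exc}") from exc
    names = g.vs["name"] if "name" in g.vs.attributes() else [str(i) for i in range(g.vcount())]
    pairs = [(names[e.source], names[e.target]) for e in g.es]
    weights = g.es["weight"] if "weight" in g.es.attributes() else np.ones(g.ecount())
    pairs, weights = _apply_negative_policy(pairs, weights, negative_policy)
    return WeightedGraph.from_edge_list(pairs, weights)


def save_graph(g: WeightedGraph, path, format: str | None = None) -> None:
    """Write a graph as edge-list TSV or GraphML."""
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMAT.get(path.suffix.lower(), "edgelist")
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for (i, j), w in zip(g.edges, g.weights):
                fh.write(f"{g.nodes[i]}\t{g.nodes[j]}\t{w:g}\n")
    elif format == "graphml":
        g.to_igraph().write_graphml(str(path))
    else:
        raise GraphFormatError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# Cost thresholding
# ---------------------------------------------------------------------------


def threshold_graph(g: WeightedGraph, cost: float) -> WeightedGraph:
    """Keep the top-weighted edges up to ``floor(cost * n(n-1)/2)`` edges.

    Every maximum-spanning-tree edge is retained (and counts toward the
    budget), so the result is always connected; if the budget is below n-1
    the result is exactly the maximum spanning tree. Weight ties at the
    cutoff are broken by the stable order of node-label pairs.
    """
    if not 0 < cost <= 1:
        raise ValueError("cost must be in (0, 1]")
    if not g.is_connected():
        raise ValueError("thresholding requires a connected graph (MST undefined)")
    budget = int(np.floor(cost * g.n * (g.n - 1) / 2))
    if budget >= g.m:
        return g

    h = g.to_igraph()
    mst = h.spanning_tree(weights=[-w for w in g.weights], return_tree=False)
    mst_mask = np.zeros(g.m, dtype=bool)
    mst_mask[mst] = True

    keep = list(np.nonzero(mst_mask)[0])
    rest = np.nonzero(~mst_mask)[0]
    order = sorted(
        rest,
        key=lambda e: (-g.weights[e], str(g.nodes[g.edges[e, 0]]), str(g.nodes[g.edges[e, 1]])),
    )
    for e in order:
        if len(keep) >= max(budget, g.n - 1):
            break
        keep.append(e)
    keep = np.array(sorted(keep), dtype=int)
    return WeightedGraph(g.nodes, g.edges[keep], g.weights[keep])


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------


def _double_edge_swap(edges: np.ndarray, n: int, attempts: int, rng) -> tuple[np.ndarray, int]:
    """Iterated degree-preserving double edge swaps.

    Weights stay attached to their edge slot, so in topology-only mode each
    weight travels with one of the rewired stubs. Returns the rewired edge
    array and the number of successful swaps.
    """
    from ._kernels import double_edge_swap_kernel

    m = len(edges)
    e1 = rng.integers(0, m, size=attempts)
    e2 = rng.integers(0, m, size=attempts)
    orient = rng.integers(0, 2, size=attempts).astype(np.bool_)
    work = edges.astype(np.int64).copy()
    adj = np.zeros((n, n), dtype=np.bool_)
    adj[work[:, 0], work[:, 1]] = True
    adj[work[:, 1], work[:, 0]] = True
    successes = double_edge_swap_kernel(work, adj, e1, e2, orient)
    return work, int(successes)


def randomize(
    g: WeightedGraph,
    size: int = 1000,
    mode: str = "topology",
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Build a null ensemble of degree-preserving randomizations of ``g``.

    mode="topology" rewires edges by double edge swaps only; mode
    "topology+weights" additionally shuffles edge weights among edges whose
    endpoint-degree pairs match, so both edge placement and weight placement
    are discounted by the null. Deterministic under a fixed seed.
    """
    if g.m < 1:
        raise ValueError("cannot randomize a graph with no edges")
    if mode not in ("topology", "topology+weights"):
        raise ValueError("mode must be 'topology' or 'topology+weights'")
    rng = np.random.default_rng(seed)
    attempts = max(swaps_per_edge * g.m, 1)
    degree = g.degree()
    # degree-pair groups for weight shuffling (degrees are preserved by swaps)
    members = []
    warned = False
    for _ in range(size):
        new_edges, successes = _double_edge_swap(g.edges, g.n, attempts, rng)
        if successes == 0 and not warned:
            warnings.warn(
                "no degree-preserving swap possible; null members equal the source topology",
                stacklevel=2,
            )
            warned = True
        weights = g.weights.copy()
        if mode == "topology+weights" and not g.is_binary:
            du = degree[new_edges[:, 0]]
            dv = degree[new_edges[:, 1]]
            key = np.minimum(du, dv) * (g.n + 1) + np.maximum(du, dv)
            for k in np.unique(key):
                idx = np.nonzero(key == k)[0]
                if len(idx) > 1:
                    weights[idx] = weights[rng.permutation(idx)]
        members.append(WeightedGraph(g.nodes, new_edges, weights))
    return NullEnsemble(source=g, graphs=members, mode=mode, seed=seed)
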