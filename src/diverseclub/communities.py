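"""Uniform interface to the nine community-detection algorithms.

The algorithms themselves are delegated to python-igraph; this module only
standardizes their invocation (seeding, binarization where required,
dendrogram cutting) and the sweep grids used to probe robustness across
densities, resolution parameters and community counts.

Algorithm notes
---------------
* ``edge_betweenness`` always receives a binarized copy of the graph: the
  algorithm removes edges on shortest paths, and weighted shortest paths
  would minimize the *sum* of weights, which has no natural reading for
  correlation networks.
* ``louvain_resolution`` is modularity maximization with the resolution
  parameter gamma swept over a grid. This approximates the stability-based
  Louvain variant through its resolution interface; exact equivalence to the
  dynamical-stability formulation is not claimed.
* ``walktrap_n`` cuts the Walktrap dendrogram at the requested community
  count, or at the maximum recorded merges, whichever happens first.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import WeightedGraph, threshold_graph

__all__ = ["Partition", "ALGORITHMS", "detect", "sweep"]

ALGORITHMS = (
    "infomap",
    "louvain",
    "louvain_resolution",
    "leading_eigenvector",
    "label_propagation",
    "edge_betweenness",
    "spin_glass",
    "walktrap",
    "walktrap_n",
)

_ALIASES = {"spectral": "leading_eigenvector", "louvain-resolution": "louvain_resolution",
            "walktrap-n": "walktrap_n", "spinglass": "spin_glass"}

_PATH_BASED = {"edge_betweenness", "spin_glass", "walktrap", "walktrap_n", "infomap"}


@dataclass
class Partition:
    """Assignment of every node of a graph to exactly one community.

    ``membership[i]`` is the community index (contiguous ``0..n_communities-1``)
    of node ``graph.nodes[i]``. Provenance (algorithm name, parameters, seed)
    is kept so sweeps remain auditable.
    """

    graph: WeightedGraph
    membership: np.ndarray
    algorithm: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        mem = np.asarray(self.membership, dtype=np.int64).reshape(-1)
        if len(mem) != self.graph.n:
            raise ValueError("membership length does not match graph size")
        # relabel to contiguous indices in order of first appearance
        _, mem = np.unique(mem, return_inverse=True)
        first = {}
        relab = np.empty_like(mem)
        nxt = 0
        for i, c in enumerate(mem):
            if c not in first:
                first[c] = nxt
                nxt += 1
            relab[i] = first[c]
        self.membership = relab

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1

    def community_of(self, node) -> int:
        return int(self.membership[self.graph.index_of(node)])

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_communities)

    def as_dict(self) -> dict:
        return {lab: int(c) for lab, c in zip(self.graph.nodes, self.membership)}


def detect(g: WeightedGraph, algorithm: str, params: dict | None = None, seed: int = 0) -> Partition:
    """Run one community-detection algorithm and return a validated Partition.

    Stochastic algorithms are seeded through Python's random module (igraph's
    default RNG), so a fixed seed reproduces the partition exactly.
    """
    params = dict(params or {})
    name = _ALIASES.get(algorithm, algorithm)
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if name in _PATH_BASED and not g.is_connected():
        raise ValueError(f"{name} requires a connected graph")

    random.seed(seed)
    weighted = not g.is_binary
    h = g.to_igraph(weighted=weighted)
    weights = h.es["weight"] if weighted else None

    if name == "infomap":
        cl = h.community_infomap(edge_weights=weights, trials=int(params.get("trials", 10)))
    elif name == "louvain":
        cl = h.community_multilevel(weights=weights, resolution=float(params.get("resolution", 1.0)))
    elif name == "louvain_resolution":
        if "resolution" not in params:
            raise ValueError("louvain_resolution requires a 'resolution' parameter")
        cl = h.community_multilevel(weights=weights, resolution=float(params["resolution"]))
    elif name == "leading_eigenvector":
        cl = h.community_leading_eigenvector(weights=weights)
    elif name == "label_propagation":
        cl = h.community_label_propagation(weights=weights)
    elif name == "edge_betweenness":
        hb = g.to_igraph(weighted=False)  # binary edges for path-based removal
        dend = hb.community_edge_betweenness(directed=False)
        cl = dend.as_clustering()
    elif name == "spin_glass":
        # annealing restarts: keep the best-modularity configuration
        best, best_q = None, -np.inf
        for r in range(int(params.get("restarts", 5))):
            random.seed(seed + r)
            cand = h.community_spinglass(weights=weights, spins=int(params.get("spins", 25)))
            q = h.modularity(cand.membership, weights=weights)
            if q > best_q:
                best, best_q = cand, q
        cl = best
    elif name == "walktrap":
        dend = h.community_walktrap(weights=weights, steps=int(params.get("steps", 4)))
        cl = dend.as_clustering()
    else:  # walktrap_n
        requested = int(params.get("n_communities", 2))
        if requested > g.n:
            raise ValueError("requested community count exceeds node count")
        dend = h.community_walktrap(weights=weights, steps=int(params.get("steps", 4)))
        floor = h.vcount() - len(dend.merges)  # fewest communities the merges reach
        cl = dend.as_clustering(max(requested, floor))

    part = Partition(graph=g, membership=np.asarray(cl.membership),
                     algorithm=name, params={**params, "seed": seed})
    return part


def sweep(g_or_graphs, algorithm: str, grid, seed: int = 0) -> list:
    """Apply one algorithm across a parameter grid, one Partition per point.

    Grid points are dicts; a ``cost`` key thresholds the graph to that density
    first (functional-network style sweeps), a ``run`` key only varies the
    seed (structural-network style repeats). A list of graphs runs the full
    grid on each. Failures at individual points are reported as warnings and
    skipped rather than aborting the sweep.
    """
    graphs = g_or_graphs if isinstance(g_or_graphs, (list, tuple)) else [g_or_graphs]
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    out = []
    i = 0
    for g in graphs:
        for point in grid:
            point = dict(point)
            try:
                target = threshold_graph(g, point["cost"]) if "cost" in point else g
                extra = {k: v for k, v in point.items() if k not in ("cost", "run")}
                part = detect(target, algorithm, extra, seed=seed + i)
                part.params.update(point)
                out.append(part)
            except Exception as exc:
                warnings.warn(f"sweep point {point} failed: {exc}", stacklevel=2)
            i += 1
    return out
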