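"""Nodal role metrics: degree, strength, and the participation coefficient.

Strength k_i is the sum of a node's incident edge weights (equal to degree on
binary graphs). Given a partition into N_M communities, the participation
coefficient is

    PC_i = 1 - sum_s (K_is / K_i)^2

where K_is is node i's summed weight into community s. PC is 0 when all of a
node's weight stays in one community and approaches 1 - 1/N_M when spread
perfectly evenly; it is independent of strength by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Partition
from .graph import WeightedGraph

__all__ = [
    "NodeProfile",
    "strength",
    "degree",
    "community_strength",
    "participation_coefficient",
    "profile_all",
    "profiles_frame",
]


@dataclass
class NodeProfile:
    node: object
    degree: int
    strength: float
    community_strength: np.ndarray
    participation: float
    community: int


def strength(g: WeightedGraph, node=None):
    """Strength of one node, or the full vector in node order."""
    k = g.strength()
    return k if node is None else float(k[g.index_of(node)])


def degree(g: WeightedGraph, node=None):
    d = g.degree()
    return d if node is None else int(d[g.index_of(node)])


def community_strength(g: WeightedGraph, p: Partition) -> np.ndarray:
    """(n, N_M) matrix K_is of summed incident weight into each community."""
    _check(g, p)
    c = p.membership
    ks = np.zeros((g.n, p.n_communities))
    u, v, w = g.edges[:, 0], g.edges[:, 1], g.weights
    np.add.at(ks, (u, c[v]), w)
    np.add.at(ks, (v, c[u]), w)
    return ks


def participation_coefficient(g: WeightedGraph, p: Partition, node=None):
    """PC_i = 1 - sum_s (K_is/K_i)^2; zero-strength nodes get PC = 0 (warned).

    Returns the full vector in node order, or a scalar for one node.
    """
    ks = community_strength(g, p)
    k = ks.sum(axis=1)
    pc = np.zeros(g.n)
    ok = k > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} isolated node(s): participation set to 0", stacklevel=2
        )
    pc[ok] = 1.0 - np.sum((ks[ok] / k[ok, None]) ** 2, axis=1)
    return pc if node is None else float(pc[g.index_of(node)])


def profile_all(g: WeightedGraph, p: Partition) -> list:
    """One NodeProfile per node; the vectorized equivalent of per-node calls."""
    _check(g, p)
    ks = community_strength(g, p)
    k = ks.sum(axis=1)
    deg = g.degree()
    pc = np.zeros(g.n)
    ok = k > 0
    pc[ok] = 1.0 - np.sum((ks[ok] / k[ok, None]) ** 2, axis=1)
    return [
        NodeProfile(
            node=lab,
            degree=int(deg[i]),
            strength=float(k[i]),
            community_strength=ks[i],
            participation=float(pc[i]),
            community=int(p.membership[i]),
        )
        for i, lab in enumerate(g.nodes)
    ]


def profiles_frame(g: WeightedGraph, p: Partition) -> pd.DataFrame:
    """Tidy table: node, degree, strength, participation, community."""
    profs = profile_all(g, p)
    return pd.DataFrame(
        {
            "node": [q.node for q in profs],
            "degree": [q.degree for q in profs],
            "strength": [q.strength for q in profs],
            "participation": [q.participation for q in profs],
            "community": [q.community for q in profs],
        }
    )


def _check(g: WeightedGraph, p: Partition) -> None:
    if p.graph is not g and (p.graph.nodes != g.nodes):
        raise ValueError("partition does not cover this graph's nodes")
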