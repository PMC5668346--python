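"""Simulated attacks on intra-club edges.

Each lesion iteration draws a target fraction of a club's intra-club edges,
removes them in random order while skipping any removal that would split the
graph, and records the resulting increase of the all-pairs shortest-path sum.
Shortest paths are always binary: efficiency is carried as

    E_G = - sum_{i<j} d(i, j)

so larger E means shorter paths, and removing edges can only decrease E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import build_csr, pathsum as _pathsum_kernel
from .clubs import Club, _member_mask
from .graph import WeightedGraph

__all__ = ["LesionOutcome", "path_sum", "efficiency", "lesion_club", "outcomes_frame"]


def path_sum(g: WeightedGraph) -> int:
    """Sum of binary shortest-path lengths over all unordered node pairs."""
    indptr, indices = build_csr(g.n, g.edges)
    total = _pathsum_kernel(g.n, indptr, indices)
    if total < 0:
        raise ValueError("path sum undefined: graph is disconnected")
    return int(total)


def efficiency(g: WeightedGraph) -> int:
    """E = -path_sum(g); larger is more efficient."""
    return -path_sum(g)


@dataclass
class LesionOutcome:
    club_metric: str
    fraction_target: float
    target_edges: int
    removed_edges: int
    delta_path_sum: int
    iteration: int
    seed: int
    complete: bool  # False when disconnection-skips prevented reaching the target


def lesion_club(
    g: WeightedGraph,
    club: Club,
    frac_range: tuple[float, float] = (0.5, 0.9),
    iterations: int = 10_000,
    seed: int = 0,
) -> list:
    """Repeatedly lesion intra-club edges and measure the path-sum increase.

    Per iteration a removal fraction is drawn uniformly from ``frac_range``,
    the intra-club edges are shuffled, and edges are removed one at a time —
    skipping (and keeping) any edge whose removal would disconnect the graph
    — until the target count is reached. The graph is restored between
    iterations; with a fixed seed the outcome list is reproducible.
    """
    if not g.is_connected():
        raise ValueError("lesioning requires a connected graph")
    lo, hi = frac_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("frac_range must satisfy 0 <= lo <= hi <= 1")
    mask = _member_mask(g, club)
    intra = np.nonzero(mask[g.edges[:, 0]] & mask[g.edges[:, 1]])[0]
    if len(intra) == 0:
        raise ValueError("club has no intra-club edges")

    rng = np.random.default_rng(seed)
    base = path_sum(g)
    n_intra = len(intra)
    outcomes = []
    for it in range(iterations):
        frac = float(rng.uniform(lo, hi))
        target = int(round(frac * n_intra))
        order = rng.permutation(intra)
        edges = g.edges.copy()
        alive = np.ones(g.m, dtype=bool)
        removed = 0
        for e in order:
            if removed >= target:
                break
            alive[e] = False
            indptr, indices = build_csr(g.n, edges[alive])
            total = _pathsum_kernel(g.n, indptr, indices)
            if total < 0:  # would disconnect: skip this edge
                alive[e] = True
            else:
                removed += 1
                after = total
        after = base if removed == 0 else after
        outcomes.append(
            LesionOutcome(
                club_metric=club.metric,
                fraction_target=frac,
                target_edges=target,
                removed_edges=removed,
                delta_path_sum=int(after - base),
                iteration=it,
                seed=seed,
                complete=removed >= target,
            )
        )
    return outcomes


def outcomes_frame(outcomes) -> pd.DataFrame:
    """Tidy table of lesion outcomes."""
    return pd.DataFrame(
        {
            "club": [o.club_metric for o in outcomes],
            "fraction": [o.fraction_target for o in outcomes],
            "target": [o.target_edges for o in outcomes],
            "removed": [o.removed_edges for o in outcomes],
            "delta_path_sum": [o.delta_path_sum for o in outcomes],
            "iteration": [o.iteration for o in outcomes],
            "seed": [o.seed for o in outcomes],
            "complete": [o.complete for o in outcomes],
        }
    )
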