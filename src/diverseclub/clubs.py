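"""Club extraction and club-level comparisons.

A *club* is the set of nodes at or above a percentile (or rank) threshold of
a nodal metric: strength gives the rich club, participation coefficient the
diverse club. Clubness theta is the summed intra-club edge weight divided by
the number of possible intra-club pairs; it is normalized against the mean
theta of the same node set in degree-preserving randomized graphs
(theta_norm = theta / theta_rand, values > 1 mean above-chance
interconnection). A supplementary variant additionally divides the deviation
by the null SD: theta_norm_sd = (theta - mean) / sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .communities import Partition
from .graph import NullEnsemble, WeightedGraph

__all__ = [
    "Club",
    "ClubnessCurve",
    "make_club",
    "clubness",
    "normalized_clubness",
    "clubness_curve",
    "club_overlap",
    "community_coverage",
    "club_betweenness",
    "intra_club_edge_betweenness",
    "BetweennessComparison",
]


@dataclass(frozen=True)
class Club:
    """A named node subset defined by thresholding a nodal metric."""

    metric: str
    members: frozenset
    threshold_value: float
    universe: tuple
    percentile: float | None = None
    rank: int | None = None
    source_partition: Partition | None = field(default=None, compare=False)

    @property
    def size(self) -> int:
        return len(self.members)


def _as_series(metric_values) -> pd.Series:
    if isinstance(metric_values, pd.Series):
        return metric_values.astype(float)
    if isinstance(metric_values, Mapping):
        return pd.Series(metric_values, dtype=float)
    raise TypeError("metric_values must be a node->value mapping or pandas Series")


def make_club(
    metric_values,
    percentile: float | None = None,
    rank: int | None = None,
    metric: str = "",
    source_partition: Partition | None = None,
) -> Club:
    """Threshold a node->value map into a Club.

    With ``percentile`` p (0 < p < 100) the club nominally holds the top
    ``ceil(n * (100-p)/100)`` nodes; with ``rank`` r it holds the ``n - r``
    nodes whose value is >= the (n-r)-th highest value. Ties spanning the
    cutoff are all included, so the actual size can exceed the nominal one.
    """
    vals = _as_series(metric_values)
    n = len(vals)
    if vals.nunique() < 2:
        raise ValueError("all metric values identical: no club separable")
    if (percentile is None) == (rank is None):
        raise ValueError("specify exactly one of percentile or rank")
    if percentile is not None:
        if not 0 < percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        k = int(np.ceil(n * (100.0 - percentile) / 100.0))
    else:
        if not 0 <= rank <= n - 2:
            raise ValueError(f"rank must be in [0, {n - 2}]")
        k = n - rank
    k = max(k, 1)
    threshold = np.sort(vals.to_numpy())[::-1][k - 1]
    members = frozenset(vals.index[vals.to_numpy() >= threshold])
    return Club(
        metric=metric,
        members=members,
        threshold_value=float(threshold),
        universe=tuple(vals.index),
        percentile=percentile,
        rank=rank,
        source_partition=source_partition,
    )


def _member_mask(g: WeightedGraph, club: Club) -> np.ndarray:
    mask = np.zeros(g.n, dtype=bool)
    for node in club.members:
        mask[g.index_of(node)] = True
    return mask


def clubness(g: WeightedGraph, club: Club) -> float:
    """theta = (summed weight of intra-club edges) / (|club| choose 2)."""
    if club.size < 2:
        raise ValueError("clubness needs at least 2 members")
    mask = _member_mask(g, club)
    intra = mask[g.edges[:, 0]] & mask[g.edges[:, 1]]
    e = float(g.weights[intra].sum())
    return e / (club.size * (club.size - 1) / 2)


def normalized_clubness(
    g: WeightedGraph, club: Club, ensemble: NullEnsemble
) -> tuple[float, float]:
    """(theta_norm, theta_norm_sd) of a fixed node set against a null ensemble.

    Membership is held fixed: the same node set is evaluated in every
    randomized graph. Returns (nan, nan) with a warning when the null mean
    is zero (theta_norm undefined).
    """
    theta = clubness(g, club)
    thetas = np.array([clubness(h, club) for h in ensemble.graphs])
    mean = thetas.mean()
    sd = thetas.std(ddof=1) if len(thetas) > 1 else 0.0
    if mean == 0:
        warnings.warn("null mean clubness is 0: theta_norm undefined", stacklevel=2)
        return float("nan"), float("nan")
    norm_sd = (theta - mean) / sd if sd > 0 else float("nan")
    return theta / mean, norm_sd


@dataclass
class ClubnessCurve:
    """Per-rank clubness with its null normalization."""

    metric: str
    ranks: np.ndarray
    sizes: np.ndarray
    theta: np.ndarray
    theta_rand_mean: np.ndarray
    theta_rand_sd: np.ndarray
    theta_norm: np.ndarray
    theta_norm_sd: np.ndarray
    ensemble_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "rank": self.ranks,
                "size": self.sizes,
                "theta": self.theta,
                "theta_rand_mean": self.theta_rand_mean,
                "theta_rand_sd": self.theta_rand_sd,
                "theta_norm": self.theta_norm,
                "theta_norm_sd": self.theta_norm_sd,
            }
        )


def _theta_by_rank(g: WeightedGraph, counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """theta per rank index given per-node counts of ranks they belong to.

    ``counts[i]`` = number of leading rank indices whose club contains node i
    (clubs shrink as ranks ascend, so membership is a prefix of the rank
    list). Vectorized over all ranks via a suffix sum of binned edge weights.
    """
    r = len(sizes)
    ecnt = np.minimum(counts[g.edges[:, 0]], counts[g.edges[:, 1]])
    binned = np.bincount(ecnt, weights=g.weights, minlength=r + 1)
    # num[j] = total weight of edges present in clubs at rank index j
    num = np.cumsum(binned[::-1])[::-1][1:]
    denom = sizes * (sizes - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(sizes >= 2, num / denom, np.nan)
    return theta


def clubness_curve(
    g: WeightedGraph,
    metric_values,
    ensemble: NullEnsemble,
    ranks=None,
    metric: str = "",
) -> ClubnessCurve:
    """Clubness at every rank, normalized by a shared null ensemble.

    Clubs are re-derived per rank from the metric values; the same ensemble
    serves every rank. Ranks whose club holds fewer than 2 nodes are
    reported as missing (NaN).
    """
    vals = _as_series(metric_values)
    if tuple(vals.index) != tuple(g.nodes):
        vals = vals.reindex(list(g.nodes))
        if vals.isna().any():
            raise ValueError("metric values do not cover the graph's nodes")
    v = vals.to_numpy()
    n = g.n
    if ranks is None:
        ranks = np.arange(1, n - 1)
    ranks = np.asarray(ranks, dtype=int)
    if len(ranks) == 0 or ranks.min() < 0 or ranks.max() > n - 2:
        raise ValueError("ranks must be a non-empty sequence within [0, n-2]")
    if np.any(np.diff(ranks) <= 0):
        ranks = np.unique(ranks)

    sorted_desc = np.sort(v)[::-1]
    thresholds = sorted_desc[n - ranks - 1]  # metric value at each rank's cutoff
    sizes = np.searchsorted(-sorted_desc, -thresholds, side="right")
    counts = np.searchsorted(thresholds, v, side="right")

    theta = _theta_by_rank(g, counts, sizes)
    rand = np.array([_theta_by_rank(h, counts, sizes) for h in ensemble.graphs])
    rand_mean = rand.mean(axis=0)
    rand_sd = rand.std(axis=0, ddof=1) if len(rand) > 1 else np.zeros_like(rand_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_norm = np.where(rand_mean > 0, theta / rand_mean, np.nan)
        theta_norm_sd = np.where(rand_sd > 0, (theta - rand_mean) / rand_sd, np.nan)
    return ClubnessCurve(
        metric=metric,
        ranks=ranks,
        sizes=sizes,
        theta=theta,
        theta_rand_mean=rand_mean,
        theta_rand_sd=rand_sd,
        theta_norm=theta_norm,
        theta_norm_sd=theta_norm_sd,
        ensemble_size=ensemble.size,
    )


def club_overlap(a: Club, b: Club) -> float:
    """Percent overlap: 100 * |a & b| / min(|a|, |b|); 100 means identical."""
    if a.size == 0 or b.size == 0:
        raise ValueError("overlap of an empty club is undefined")
    if set(a.universe) != set(b.universe):
        raise ValueError("clubs live on different node universes")
    return 100.0 * len(a.members & b.members) / min(a.size, b.size)


def community_coverage(club: Club, p: Partition) -> float:
    """Percentage of communities containing at least one club member."""
    covered = {p.community_of(node) for node in club.members}
    return 100.0 * len(covered) / p.n_communities


@dataclass
class BetweennessComparison:
    """Two-sample (Welch) comparison of a centrality between club and rest."""

    values: pd.Series
    club_mean: float
    rest_mean: float
    t: float
    p: float
    cohen_d: float


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    if len(a) < 2 or len(b) < 2:  # comparison undefined, centrality values still useful
        return float("nan"), float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else float("nan")
    return float(t), float(p), float(d)


def club_betweenness(g: WeightedGraph, club: Club) -> BetweennessComparison:
    """Node betweenness (binary shortest paths) of members vs. non-members."""
    if not g.is_connected():
        raise ValueError("betweenness comparison requires a connected graph")
    h = g.to_igraph(weighted=False)
    btw = np.array(h.betweenness())
    mask = _member_mask(g, club)
    t, p, d = _welch(btw[mask], btw[~mask])
    return BetweennessComparison(
        values=pd.Series(btw, index=list(g.nodes)),
        club_mean=float(btw[mask].mean()),
        rest_mean=float(btw[~mask].mean()),
        t=t,
        p=p,
        cohen_d=d,
    )


def intra_club_edge_betweenness(g: WeightedGraph, club: Club) -> BetweennessComparison:
    """Edge betweenness (binary) of intra-club edges vs. all other edges."""
    if not g.is_connected():
        raise ValueError("edge betweenness comparison requires a connected graph")
    h = g.to_igraph(weighted=False)
    ebt = np.array(h.edge_betweenness())
    mask = _member_mask(g, club)
    intra = mask[g.edges[:, 0]] & mask[g.edges[:, 1]]
    if not intra.any():
        raise ValueError("club has no intra-club edges")
    t, p, d = _welch(ebt[intra], ebt[~intra])
    labels = [(g.nodes[i], g.nodes[j]) for i, j in g.edges]
    return BetweennessComparison(
        values=pd.Series(ebt, index=pd.MultiIndex.from_tuples(labels)),
        club_mean=float(ebt[intra].mean()),
        rest_mean=float(ebt[~intra].mean()) if (~intra).any() else float("nan"),
        t=t,
        p=p,
        cohen_d=d,
    )
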