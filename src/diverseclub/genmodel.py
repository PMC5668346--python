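"""Generative evolutionary model trading off modularity against efficiency.

The model starts from a random binary graph (default 100 nodes, 5% of
possible edges = 247) and, for a fixed number of iterations, removes the
batch of edges whose removal jointly increases modularity Q the most and
decreases efficiency E the least, then places the same number of edges back
uniformly at random — edge count stays constant throughout. Selection uses
competition-ranked, z-scored vectors of per-edge dQ and dE combined by the
Q-ratio weight (0.5 = both objectives equally, 1 = Q only). A null variant
selects the removed edges uniformly at random.

Modularity follows the resolution-parameterized configuration-null form

    Q = (1/2m) sum_ij (A_ij - gamma * k_i k_j / 2m) delta(c_i, c_j)

and efficiency is the negated binary all-pairs path sum, E = -sum d(i, j),
so both objectives are "larger is better".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import stats

from ._kernels import bfs_all, build_csr, delta_pathsums, pathsum as _pathsum_kernel
from .clubs import clubness_curve
from .communities import Partition, detect
from .graph import WeightedGraph, randomize
from .metrics import participation_coefficient

__all__ = [
    "ModelConfig",
    "ModelTrace",
    "EdgeScores",
    "DistributionFit",
    "fit_distributions",
    "modularity_Q",
    "competition_rank",
    "edge_objective",
    "run_model",
    "run_null",
    "run_ensemble",
    "stability_diagnostics",
    "StabilityReport",
    "kld_fit",
    "compare_model_vs_null",
    "ModelClubComparison",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one generative-model run.

    Defaults reproduce the reference setting: 100 nodes at density 0.05
    (m0 = 247 edges), batches of ceil(0.05 * m0) = 13 edges, 150 iterations
    (13 * 150 = 1950 edges shuffled in total).
    """

    n_nodes: int = 100
    density: float = 0.05
    q_ratio: float = 0.75
    iterations: int = 150
    batch_fraction: float = 0.05
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.5 <= self.q_ratio <= 1.0:
            raise ValueError("q_ratio must be in [0.5, 1.0]")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.n_nodes < 3 or self.iterations < 1:
            raise ValueError("invalid model size")

    @property
    def m0(self) -> int:
        return int(np.floor(self.density * self.n_nodes * (self.n_nodes - 1) / 2))

    @property
    def batch_size(self) -> int:
        return int(np.ceil(self.batch_fraction * self.m0))

    @property
    def total_shuffled(self) -> int:
        return self.batch_size * self.iterations


@dataclass
class ModelTrace:
    """Per-iteration record of one model run (initial state included)."""

    Q_series: np.ndarray
    E_series: np.ndarray
    final_graph: WeightedGraph
    config: ModelConfig
    is_null: bool


def modularity_Q(g: WeightedGraph, p: Partition, gamma: float = 1.0) -> float:
    """Resolution-parameterized modularity of a partition.

    Standard configuration-null form: Q = (1/2m) sum_ij (A_ij - gamma
    k_i k_j / 2m) delta(c_i, c_j), the null term running over all ordered
    pairs (self-pairs contribute k_i^2/2m to the null as in the
    configuration model; A_ii = 0). This is the definition community
    detection toolkits maximize. For weighted graphs ``m`` is read as the
    total edge weight.
    """
    if g.m == 0:
        raise ValueError("modularity undefined on an empty graph")
    c = p.membership
    w2 = 2.0 * g.weights.sum()
    intra = float(g.weights[c[g.edges[:, 0]] == c[g.edges[:, 1]]].sum())
    dsum = np.zeros(p.n_communities)
    np.add.at(dsum, c, g.strength())
    return 2.0 * intra / w2 - gamma * float(np.sum((dsum / w2) ** 2))


def competition_rank(x) -> np.ndarray:
    """Ascending competition ("min") ranks: ties all get the smallest rank."""
    return stats.rankdata(np.asarray(x, dtype=float), method="min").astype(np.int64)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population SD; all-tied vectors map to zeros
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


@dataclass
class EdgeScores:
    """Per-edge joint removal objective for one graph/partition state."""

    edges: np.ndarray
    delta_q: np.ndarray
    delta_e: np.ndarray
    is_bridge: np.ndarray
    score: np.ndarray


def _delta_q_all(g_edges, membership, degrees, m, intra_flags, dsum, gamma) -> np.ndarray:
    """dQ(e) = Q(g - e) - Q(g) for every (binary) edge, partition held fixed.

    Removing edge (u, v) lowers the two endpoint communities' degree sums by
    one each (by two for an intra-community edge), so the configuration-null
    term shifts in closed form.
    """
    sum_d2 = float(np.sum(dsum.astype(float) ** 2))
    intra_total = float(intra_flags.sum())
    cu = membership[g_edges[:, 0]]
    cv = membership[g_edges[:, 1]]
    du = dsum[cu].astype(float)
    dv = dsum[cv].astype(float)
    same = cu == cv
    new_sum_d2 = np.where(
        same, sum_d2 - 4.0 * du + 4.0, sum_d2 - 2.0 * du + 1.0 - 2.0 * dv + 1.0
    )
    new_intra = intra_total - same.astype(float)
    m2 = 2.0 * (m - 1)
    q_old = 2.0 * intra_total / (2.0 * m) - gamma * sum_d2 / (2.0 * m) ** 2
    q_new = 2.0 * new_intra / m2 - gamma * new_sum_d2 / m2**2
    return q_new - q_old


def edge_objective(g: WeightedGraph, p: Partition, q_ratio: float, gamma: float = 1.0) -> EdgeScores:
    """Joint per-edge removal score: q_ratio * z(rank dQ) + (1-q_ratio) * z(rank dE).

    dQ and dE are the changes from removing that single edge (partition held
    fixed for dQ); both vectors are competition-ranked ascending so larger
    improvement earns a larger rank, then z-scored. Bridges — removals that
    would disconnect the graph — get ``-inf`` so they are never selected.
    """
    if not 0.5 <= q_ratio <= 1.0:
        raise ValueError("q_ratio must be in [0.5, 1.0]")
    if not g.is_connected():
        raise ValueError("edge_objective requires a connected graph")
    if not g.is_binary:
        raise ValueError("the generative objective is defined on binary graphs")
    edges = g.edges
    membership = p.membership
    degrees = g.degree()
    dsum = np.zeros(p.n_communities)
    np.add.at(dsum, membership, degrees.astype(float))
    intra_flags = membership[edges[:, 0]] == membership[edges[:, 1]]
    dq = _delta_q_all(edges, membership, degrees, g.m, intra_flags, dsum, gamma)

    indptr, indices = build_csr(g.n, edges)
    h = g.to_igraph(weighted=False)
    is_bridge = np.zeros(g.m, dtype=bool)
    is_bridge[h.bridges()] = True
    D, S = bfs_all(g.n, indptr, indices)
    dps = delta_pathsums(g.n, indptr, indices, edges.astype(np.int64), D, S, is_bridge)
    de = np.where(is_bridge, np.nan, -dps.astype(float))  # E = -path sum

    ok = ~is_bridge
    score = np.full(g.m, -np.inf)
    if ok.any():
        zq = _zscore(competition_rank(dq[ok]).astype(float))
        ze = _zscore(competition_rank(de[ok]).astype(float))
        score[ok] = q_ratio * zq + (1.0 - q_ratio) * ze
    return EdgeScores(edges=edges, delta_q=dq, delta_e=de, is_bridge=is_bridge, score=score)


# ---------------------------------------------------------------------------
# Model runners
# ---------------------------------------------------------------------------


def _connected_er_edges(n: int, m: int, rng) -> np.ndarray:
    """Exactly-m-edge ER draw, resampled until connected."""
    npairs = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(10_000):
        pick = rng.choice(npairs, size=m, replace=False)
        edges = np.column_stack([iu[pick], ju[pick]]).astype(np.int64)
        indptr, indices = build_csr(n, edges)
        if _pathsum_kernel(n, indptr, indices) >= 0:
            return edges
    raise RuntimeError("could not draw a connected initial graph")


def _graph_from_edges(n: int, edges: np.ndarray) -> WeightedGraph:
    return WeightedGraph(tuple(str(i) for i in range(n)), edges, np.ones(len(edges)))


def _remove_with_skip(edges: np.ndarray, order, batch: int, n: int) -> tuple[np.ndarray, int]:
    """Remove up to ``batch`` edges in the given order, skipping disconnectors."""
    alive = np.ones(len(edges), dtype=bool)
    removed = 0
    for e in order:
        if removed >= batch:
            break
        alive[e] = False
        indptr, indices = build_csr(n, edges[alive])
        if _pathsum_kernel(n, indptr, indices) < 0:
            alive[e] = True
        else:
            removed += 1
    return edges[alive], removed


def _add_random_edges(edges: np.ndarray, count: int, n: int, rng) -> np.ndarray:
    present = set(map(tuple, edges.tolist()))
    new = []
    while len(new) < count:
        u = int(rng.integers(0, n))
        v = int(rng.integers(0, n))
        if u == v:
            continue
        key = (u, v) if u < v else (v, u)
        if key in present:
            continue
        present.add(key)
        new.append(key)
    return np.vstack([edges, np.array(new, dtype=np.int64)])


def _run(config: ModelConfig, null: bool) -> ModelTrace:
    rng = np.random.default_rng(config.seed)
    n, m0, batch = config.n_nodes, config.m0, config.batch_size
    edges = _connected_er_edges(n, m0, rng)

    q_series, e_series = [], []
    for _ in range(config.iterations):
        g = _graph_from_edges(n, edges)
        edges = g.edges  # canonical order: scores below index into this array
        part = detect(g, "louvain", {"resolution": config.gamma},
                      seed=int(rng.integers(2**31)))
        q_series.append(modularity_Q(g, part, config.gamma))
        indptr, indices = build_csr(n, edges)
        e_series.append(-int(_pathsum_kernel(n, indptr, indices)))

        if null:
            order = rng.permutation(len(edges))
        else:
            scores = edge_objective(g, part, config.q_ratio, config.gamma)
            order = np.argsort(-scores.score, kind="stable")
        edges, removed = _remove_with_skip(edges, order, batch, n)
        edges = _add_random_edges(edges, removed, n, rng)
        assert len(edges) == m0, "edge count must stay constant"

    g = _graph_from_edges(n, edges)
    part = detect(g, "louvain", {"resolution": config.gamma}, seed=int(rng.integers(2**31)))
    q_series.append(modularity_Q(g, part, config.gamma))
    indptr, indices = build_csr(n, edges)
    e_series.append(-int(_pathsum_kernel(n, indptr, indices)))

    return ModelTrace(
        Q_series=np.array(q_series),
        E_series=np.array(e_series, dtype=float),
        final_graph=g,
        config=config,
        is_null=null,
    )


def run_model(config: ModelConfig) -> ModelTrace:
    """One run of the selection model (edges removed by joint Q/E objective)."""
    return _run(config, null=False)


def run_null(config: ModelConfig) -> ModelTrace:
    """One run of the random-selection null (edges removed uniformly)."""
    return _run(config, null=True)


def run_ensemble(config: ModelConfig, runs: int, null: bool = False, progress=None) -> list:
    """``runs`` independent traces; run i uses seed ``config.seed + i``."""
    traces = []
    for i in range(runs):
        cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + i})
        traces.append(_run(cfg, null=null))
        if progress is not None:
            progress(i + 1, runs)
    return traces


# ---------------------------------------------------------------------------
# Diagnostics and comparisons
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Windowed convergence diagnostics of the ensemble-mean Q and E series."""

    q_change: float  # mean absolute % change of Q over the last window
    e_change: float
    q_change_series: np.ndarray
    e_change_series: np.ndarray
    window_back: int
    window_last: int
    n_runs: int


def _windowed_change(x: np.ndarray, window_back: int) -> np.ndarray:
    out = np.full(len(x), np.nan)
    for t in range(window_back, len(x)):
        prev = x[t - window_back : t]
        out[t] = float(np.mean(np.abs((x[t] - prev) / prev)) * 100.0)
    return out


def stability_diagnostics(traces, window_back: int = 40, window_last: int = 30) -> StabilityReport:
    """Mean absolute percentage change of ensemble-mean Q and E.

    For each iteration the ensemble-mean value is compared against each of
    its previous ``window_back`` iterations; the headline scalars average
    those per-iteration changes over the final ``window_last`` iterations.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    qlen = len(traces[0].Q_series)
    if qlen < window_back + window_last:
        raise ValueError("series shorter than the diagnostic windows")
    qbar = np.mean([t.Q_series for t in traces], axis=0)
    ebar = np.mean([t.E_series for t in traces], axis=0)
    qc = _windowed_change(qbar, window_back)
    ec = _windowed_change(ebar, window_back)
    return StabilityReport(
        q_change=float(np.nanmean(qc[-window_last:])),
        e_change=float(np.nanmean(ec[-window_last:])),
        q_change_series=qc,
        e_change_series=ec,
        window_back=window_back,
        window_last=window_last,
        n_runs=len(traces),
    )


def kld_fit(model_values, reference_values, bins: int = 10) -> float:
    """Kullback-Leibler divergence between two binned node-metric distributions.

    Both vectors are histogrammed into ``bins`` shared bins spanning the
    pooled range; each bin holds the proportion of nodes. Returns
    KLD(P || K) = sum_i P(i) log(P(i)/K(i)) in nats (0 iff the binned
    distributions coincide; +inf when the model occupies a bin the
    reference leaves empty).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p_vals = np.asarray(model_values, dtype=float)
    k_vals = np.asarray(reference_values, dtype=float)
    if p_vals.size == 0 or k_vals.size == 0:
        raise ValueError("both metric vectors must be non-empty")
    edges = np.histogram_bin_edges(np.concatenate([p_vals, k_vals]), bins=bins)
    p_hist = np.histogram(p_vals, bins=edges)[0].astype(float)
    k_hist = np.histogram(k_vals, bins=edges)[0].astype(float)
    kld = float(stats.entropy(p_hist, k_hist))
    if np.isinf(kld):
        warnings.warn("reference leaves a populated bin empty: KLD is infinite", stacklevel=2)
    return kld


@dataclass
class DistributionFit:
    """KLD fit of a model graph's degree and PC distributions to a reference."""

    kld_degree: float
    kld_participation: float
    bins: int
    reference: str


def fit_distributions(
    g: WeightedGraph,
    p: Partition,
    reference_degree,
    reference_participation,
    bins: int = 10,
    reference: str = "user-supplied",
) -> DistributionFit:
    """KLD of a graph's degree and participation distributions vs. a reference.

    The reference vectors are any user-supplied node-metric samples (e.g.
    from an empirical network); the package bundles no empirical data.
    """
    return DistributionFit(
        kld_degree=kld_fit(g.degree(), reference_degree, bins=bins),
        kld_participation=kld_fit(
            participation_coefficient(g, p), reference_participation, bins=bins
        ),
        bins=bins,
        reference=reference,
    )


@dataclass
class ModelClubComparison:
    """Per-rank ensemble clubness of model vs. null final graphs."""

    ranks: np.ndarray
    model_diverse: np.ndarray  # (runs, ranks) theta_norm
    model_rich: np.ndarray
    null_diverse: np.ndarray
    null_rich: np.ndarray
    t_per_rank: np.ndarray  # model vs null, diverse club
    p_per_rank: np.ndarray
    top_fraction: float
    diverse_t: float  # one-sided aggregate over the top ranks
    diverse_p: float
    rich_t: float
    rich_p: float
    excluded: int


def _trace_curves(trace: ModelTrace, ranks, null_size: int, seed: int):
    g = trace.final_graph
    part = detect(g, "louvain", seed=seed)
    pc = participation_coefficient(g, part)
    k = g.strength()
    ens = randomize(g, size=null_size, mode="topology", seed=seed)
    nodes = list(g.nodes)
    div = clubness_curve(g, dict(zip(nodes, pc)), ens, ranks=ranks, metric="participation")
    rich = clubness_curve(g, dict(zip(nodes, k)), ens, ranks=ranks, metric="strength")
    return div.theta_norm, rich.theta_norm


def compare_model_vs_null(
    model_traces,
    null_traces,
    ranks=None,
    null_size: int = 100,
    seed: int = 0,
    top_fraction: float = 0.2,
) -> ModelClubComparison:
    """Clubness of diverse/rich clubs in model vs. random-selection final graphs.

    For every connected final graph a partition is detected, strength and
    participation coefficient computed, and per-rank normalized clubness
    derived against a fresh degree-preserving ensemble. Aggregates the top
    ``top_fraction`` of ranks per run and reports one-sided two-sample
    t-statistics (model > null) for each club.
    """
    model_traces, null_traces = list(model_traces), list(null_traces)
    if not model_traces or not null_traces:
        raise ValueError("both ensembles must be non-empty")
    n = model_traces[0].final_graph.n
    if ranks is None:
        ranks = np.arange(1, n - 1)
    ranks = np.asarray(ranks, dtype=int)

    excluded = 0
    rows = {"model": {"div": [], "rich": []}, "null": {"div": [], "rich": []}}
    for kind, traces in (("model", model_traces), ("null", null_traces)):
        for i, tr in enumerate(traces):
            if not tr.final_graph.is_connected():
                warnings.warn("disconnected final graph excluded from comparison", stacklevel=2)
                excluded += 1
                continue
            d, r = _trace_curves(tr, ranks, null_size, seed=seed + i)
            rows[kind]["div"].append(d)
            rows[kind]["rich"].append(r)

    md = np.array(rows["model"]["div"])
    mr = np.array(rows["model"]["rich"])
    nd = np.array(rows["null"]["div"])
    nr = np.array(rows["null"]["rich"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_per_rank, p_per_rank = stats.ttest_ind(md, nd, axis=0, equal_var=False)

    n_top = max(1, int(np.ceil(top_fraction * len(ranks))))
    agg = {key: np.nanmean(arr[:, -n_top:], axis=1) for key, arr in
           (("md", md), ("mr", mr), ("nd", nd), ("nr", nr))}
    dt, dp = stats.ttest_ind(agg["md"], agg["nd"], equal_var=False, alternative="greater")
    rt, rp = stats.ttest_ind(agg["mr"], agg["nr"], equal_var=False, alternative="greater")
    return ModelClubComparison(
        ranks=ranks,
        model_diverse=md,
        model_rich=mr,
        null_diverse=nd,
        null_rich=nr,
        t_per_rank=np.asarray(t_per_rank),
        p_per_rank=np.asarray(p_per_rank),
        top_fraction=top_fraction,
        diverse_t=float(dt),
        diverse_p=float(dp),
        rich_t=float(rt),
        rich_p=float(rp),
        excluded=excluded,
    )
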