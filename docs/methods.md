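# Methods

This note documents the models and procedures the package implements, the
defaults and why they are set where they are, the numerical choices, and
what the synthetic fixtures do and do not establish.

## Graphs, thresholding, and null ensembles

All computations run on undirected graphs with strictly positive edge
weights (`WeightedGraph`); binary graphs carry weight 1.0 on every edge.
Negative weights — e.g. negative correlations in functional connectivity
matrices — are dropped (default) or rejected at load time; they have no
interpretation in the club statistics.

**Cost thresholding** keeps the top-weighted edges up to
`floor(cost · n(n−1)/2)` edges while always retaining the maximum spanning
tree, so a thresholded graph can never disconnect; the MST edges count
toward the budget, and when the budget is below `n−1` the result is exactly
the MST. Weight ties at the cutoff are broken by the stable lexicographic
order of node-label pairs, making thresholding deterministic and idempotent
at a fixed cost.

**Null ensembles** randomize edge placement by iterated double edge swaps
(10 proposals per edge by default), which preserve every node's degree
exactly; proposals creating self-loops or duplicate edges are rejected.
Weights travel with their edge slot through swaps. In
`topology+weights` mode the weights are additionally permuted among edges
whose unordered endpoint-degree pairs match — the strictest reading of
shuffling "between nodes with the same number of edges" — so both edge and
weight placement are discounted by the null. Graphs with no degree-preserving
alternative (e.g. stars) yield ensembles equal to the source, with a
warning. All randomness in an ensemble flows through a single seeded
generator, so ensembles are bit-reproducible.

## Community detection

Nine algorithms are exposed through one interface, all delegated to
python-igraph: InfoMap, Louvain, Louvain with a swept resolution parameter,
leading-eigenvector (spectral), label propagation, edge betweenness, spin
glass, Walktrap, and Walktrap cut to a requested community count. Stochastic
algorithms are seeded through igraph's RNG so sweeps are reproducible; sweep
point *i* uses seed `base + i`. Edge betweenness always receives a binarized
copy: weighted shortest paths minimize the *sum* of weights, which is
meaningful for travel costs but not for correlation strength. The
resolution-swept Louvain stands in for the dynamical-stability Louvain
variant via its resolution interface; the two agree in spirit (a scale
parameter controlling community granularity) but not formally, and no exact
equivalence is claimed. Walktrap-N replays dendrogram merges until the
requested count or the last recorded merge, whichever comes first.

Sweep grids are configuration, not constants: density sweeps of functional
networks are conventionally 16 costs, and published descriptions vary
between 0.05–0.15 and 5–20%; the grid is therefore an argument everywhere.

## Node metrics

The participation coefficient is computed from the *weighted* graph for any
partition — including partitions produced on a binarized copy — because the
metric is defined on edge weights regardless of how the communities were
found. Isolated (zero-strength) nodes get PC = 0 with a warning rather than
NaN, so club ranking over all nodes stays total.

## Clubs and clubness

A percentile-p club nominally holds the top `ceil(n(100−p)/100)` nodes; a
rank-r club the top `n − r`. Membership is by value ≥ the cutoff value, so
ties spanning the cutoff enlarge the club — the convention that keeps the
definition purely value-based. Clubness curves evaluate every rank of an
integer grid (default 1..n−2) against one shared null ensemble (default
size 1000); the club's node set is held fixed when evaluated inside each
null graph. Ranks whose club has fewer than two members are reported
missing. θ_norm divides by the null mean; the SD-normalized variant
(θ − mean)/sd is always reported alongside. Topology-only nulls are the
default for weighted graphs, weight shuffling being the optional stricter
variant.

Club **overlap** is `100 · |A∩B| / min(|A|,|B|)`: clubs are nominally
equal-sized, but ties can unbalance them, and the min denominator preserves
"100% = identical" in the equal-size case. All betweenness quantities
(node and edge) use binary shortest paths. The member-vs-rest comparison is
a two-sided Welch t-test with Cohen's d reported; the choice of test is a
package decision — the underlying claim is only "higher/lower".

## Lesions

Each lesion iteration draws a removal fraction uniformly from the
configured range (default 0.5–0.9 of intra-club edges), shuffles the
intra-club edges, and removes them one at a time, skipping any edge whose
removal would split the graph — per-edge skipping rather than rejecting
whole iterations, which guarantees progress and keeps every recorded
outcome connected. The outcome is the increase in the binary all-pairs
path sum, which is non-negative by construction. Default 10,000 iterations;
tests and examples scale this down (200–1000) since the outcome
distributions separate long before that.

## Generative model

Defaults: 100 nodes, density 0.05 → `m0 = floor(0.05·4950) = 247` edges,
batch `ceil(0.05·247) = 13`, 150 iterations (1950 edges shuffled), Q-ratio
0.75, resolution γ = 1. The floor/ceil pair is what makes the printed
247/13 bookkeeping exact.

Per iteration: one modularity-maximizing (Louvain) partition is detected
and held fixed while scoring; ΔQ(e) = Q(g−e) − Q(g) is then a closed-form
function of the edge (community degree sums shift by one), and
ΔE(e) = E(g−e) − E(g) is computed exactly by an incremental all-pairs BFS
(distances and shortest-path counts are computed once; removing edge (u,v)
can change distances from source *i* only when every shortest path from *i*
to the far endpoint crosses that edge, so only those sources are
re-explored). Re-detecting the partition per candidate removal would change
the objective mid-scoring and is computationally prohibitive.

Both rank vectors use competition ("min") ranking ascending — a larger
increase of Q, and a smaller loss of E, earn larger ranks — then population
z-scores (an all-tied vector z-scores to zeros), combined as
`q_ratio · z_Q + (1 − q_ratio) · z_E`. Ranks are oriented so that a higher
joint score marks a more favorable removal, the only reading consistent
with selecting removals that maximally increase both objectives. Edges
whose removal disconnects the graph have no defined E and receive the worst
score. The batch is removed in score order, skipping any edge that *at that
point* would disconnect the graph (batch removals can disconnect even when
each single removal does not); replacements are drawn uniformly from absent
pairs and may re-create a removed edge. Edge count is asserted constant at
every iteration. The initial graph is an exact-m ER draw resampled until
connected — E is undefined on disconnected graphs, and at 100 nodes/247
edges a raw draw is occasionally disconnected. The random-selection null
differs only in choosing removals uniformly.

Modularity follows the standard configuration null: the null term runs over
all ordered node pairs, self-pairs included, which is the definition the
detection toolkits maximize. (Writing the modularity sum with i≠j is common
shorthand since A_ii = 0, but dropping the self-pair null contribution
changes the value and — through ΔQ — the selection dynamics; the package
uses the standard form throughout and its brute-force test oracle sums that
definition directly.)

Two readings of efficiency circulate — "the inverse" and "the negation" of
the path sum. The package implements the negated form `E = −Σ d(i,j)`
(the closed-form definition); every use of E here is ordinal (rankings,
stability in percent, trajectories), where the two readings agree.

**Stability diagnostics** average Q and E trajectories across an ensemble,
compare each iteration's value with each of its previous 40, and report the
mean absolute percentage change over the final 30 iterations. With 50+
runs at Q-ratio 0.75 both diagnostics fall below 1%; a single run does not
converge to that tolerance — the diagnostic is a property of the ensemble
mean, as the per-run fluctuations (±0.03 in Q) do not vanish.

**Distribution fits** use the Kullback–Leibler divergence between 10-bin
histograms (proportions, shared bin edges across the pooled range of both
samples); a populated model bin that is empty in the reference makes the
divergence infinite and is flagged. Any user-supplied reference vector can
serve as the comparison distribution; the package does not bundle empirical
brain data.

**Model-vs-null club comparison**: for each final graph a partition is
detected, strength and PC computed, and per-rank θ_norm derived against a
fresh degree-preserving ensemble (100 members per graph in the comparison —
smaller than the 1000 used for single-graph curves, since the quantity is
averaged over runs). Runs whose final graph is disconnected are excluded
with a diagnostic (none occur at the defaults, where connectivity is
enforced during removal). The headline comparison averages θ_norm over the
top 20% of ranks per run and tests model > null with a one-sided Welch
t-test, separately for the diverse and the rich club.

## Synthetic fixtures

The planted-partition generator (default 4 blocks × 15 nodes, p_in = 0.8,
p_out = 0.05) produces graphs whose community structure every detection
algorithm recovers exactly, plus optional bridge hubs: each bridge spreads
`bridge_degree` (default 12) edges evenly over the blocks and connects to
other bridges with probability 0.75. Bridges are the designed diverse club —
they top the PC ranking, their mutual edges give the diverse club
above-chance clubness, and their edges carry inter-community shortest
paths, so diverse-club lesions cost more efficiency than rich-club lesions.
Defaults were chosen once to put the fixture safely in the
strong-recovery/connected regime.

These fixtures establish *mechanism*, not generality: they demonstrate that
the pipeline detects designed club structure and that the documented
orderings follow from that structure. Real correlation networks differ in
ways the fixtures do not emulate (heavy-tailed strength distributions,
transitivity from the correlation construction, noise in the partition),
so passing tests do not by themselves certify behavior on empirical data.

## Known limitations

* The incremental ΔE kernel and the lesion loop assume binary shortest
  paths throughout, which is the package-wide convention; weighted-path
  variants are out of scope.
* Double-edge-swap mixing uses a fixed proposal budget (10·m), not a mixing
  diagnostic; extremely constrained degree sequences rewire little (and
  warn when they cannot rewire at all).
* The stability-Louvain variant is approximated by the resolution
  parameter, as noted above.
* `compare_model_vs_null` detects one partition per final graph; partition
  uncertainty is not propagated into the clubness curves.
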