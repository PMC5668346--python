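import numpy as np
import pytest

from diverseclub import (
    PlantedPartitionSpec,
    WeightedGraph,
    planted_partition,
)


@pytest.fixture(scope="session")
def two_cliques():
    """Two 5-cliques joined by a single bridge edge."""
    pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    pairs += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
    pairs.append((4, 5))
    return WeightedGraph.from_edge_list([(str(u), str(v)) for u, v in pairs])


@pytest.fixture(scope="session")
def planted():
    """Strong planted partition: 4 blocks of 15, p_in=0.8, p_out=0.05."""
    g, truth = planted_partition(PlantedPartitionSpec(seed=42))
    assert g.is_connected()
    return g, truth


@pytest.fixture(scope="session")
def bridge_fixture():
    """Planted partition plus 8 interconnected bridge hubs (designed diverse club).

    Each bridge serves two of the four blocks, so paths between blocks that
    share no bridge must hop across bridge-bridge edges."""
    g, truth = planted_partition(
        PlantedPartitionSpec(bridge_nodes=8, blocks_per_bridge=2, p_out=0.01, seed=7)
    )
    assert g.is_connected()
    return g, truth


@pytest.fixture()
def path_graph():
    return WeightedGraph.from_edge_list([("a", "b"), ("b", "c")])


@pytest.fixture()
def star_graph():
    return WeightedGraph.from_edge_list([("hub", f"leaf{i}") for i in range(4)])


def random_connected_graph(rng, n, p):
    """Small random connected binary graph for oracle comparisons."""
    while True:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        if mask.sum() < n - 1:
            continue
        g = WeightedGraph(
            tuple(str(i) for i in range(n)),
            np.column_stack([iu[mask], ju[mask]]),
            np.ones(int(mask.sum())),
        )
        if g.is_connected():
            return g
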