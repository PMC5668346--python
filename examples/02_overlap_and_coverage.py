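"""How distinct are the two clubs, and how many communities does each span?

Extracts the 80th-percentile rich and diverse clubs from a planted-partition
graph, then prints their percent overlap (100 = identical membership) and the
percentage of communities each club reaches (an integrative club should touch
most of them).
"""

from diverseclub import (
    PlantedPartitionSpec,
    club_overlap,
    community_coverage,
    detect,
    make_club,
    participation_coefficient,
    planted_partition,
)

g, _ = planted_partition(PlantedPartitionSpec(bridge_nodes=8, blocks_per_bridge=2, p_out=0.01, seed=7))
part = detect(g, "louvain", seed=0)
pc = participation_coefficient(g, part)
nodes = list(g.nodes)

diverse = make_club(dict(zip(nodes, pc)), percentile=80, metric="participation",
                    source_partition=part)
rich = make_club(dict(zip(nodes, g.strength())), percentile=80, metric="strength")

print(f"diverse club: {diverse.size} nodes  (PC >= {diverse.threshold_value:.3f})")
print(f"rich club:    {rich.size} nodes  (strength >= {rich.threshold_value:.0f})")
print(f"overlap: {club_overlap(diverse, rich):.1f}% of the smaller club")
print(f"community coverage, diverse: {community_coverage(diverse, part):.0f}%")
print(f"community coverage, rich:    {community_coverage(rich, part):.0f}%")
print("(the clubs share only a fifth of their members: high strength and")
print(" diverse connectivity single out different nodes in this network)")
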