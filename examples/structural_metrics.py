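"""Structural variables of a small attention network, step by step.

Builds the directed transition-count graph by hand and prints every
measure family: strength (centrality), WDC and uniformity (distribution),
cut size and cliques (interconnectedness).
"""

import networkx as nx

from gazenet import (
    AttentionNetwork, clique_stats, cut_size, group_strength,
    normalized_cut_size, outgoing_weight_profile, strength,
    to_undirected, uniformity, weighted_degree_centrality,
)

g = nx.DiGraph()
for u, v, w in [("teacher", "board", 8), ("board", "teacher", 6),
                ("teacher", "peer_a", 2), ("peer_a", "teacher", 3),
                ("peer_a", "peer_b", 1), ("board", "peer_b", 1)]:
    g.add_edge(u, v, weight=w)
net = AttentionNetwork(participant_id="demo", graph=g)

print("strength (in+out weight) per OOI:")
for node in sorted(net.nodes):
    print(f"  {node:8s} {strength(net, node):4.0f}")
print(f"front group strength (teacher+board): {group_strength(net, ['teacher', 'board']):.0f}")

profile = outgoing_weight_profile(net, "teacher")
print(f"teacher outgoing weights (sorted): {profile} "
      f"-> WDC {weighted_degree_centrality(profile):.3f} of max {len(profile)}")
print(f"uniformity U = {uniformity(net):.3f}  (0 would mean perfectly even edges)")

s, t = {"teacher", "board"}, {"peer_a", "peer_b"}
print(f"cut(front, peers) = {cut_size(net, s, t):.0f}, "
      f"normalized {normalized_cut_size(net, s, t):.3f} of all transitions")

cs = clique_stats(to_undirected(net))
print(f"maximal cliques: {cs.cliques} -> count {cs.count}, average size {cs.average_size:.2f}")
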