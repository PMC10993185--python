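"""Structural variables of gaze-based attention networks.

Three families of measures describe a participant's network:

* **Centrality** — node strength (summed in- plus out-edge weights) and
  group strength: how much gaze traffic an OOI, or a set of OOIs, attracts.
* **Distribution** — weighted degree centrality (WDC), a Lorenz-curve
  uniformity index of one node's outgoing edge weights ranging from 1
  (maximally skewed) to DC (perfectly even across all DC edges), and the
  uniformity statistic U, the negated chi-square statistic of all edge
  weights (0 = perfectly even gaze distribution, more negative = more
  concentrated).
* **Interconnectedness** — cut size across a two-set node partition
  (optionally normalized by total edge weight) and maximal cliques of the
  undirected network (count and average size).

WDC is computed on ascending-sorted weights:

    WDC = 1 + 2 * sum_{i=1}^{DC-1} Fc(i),   Fc(i) = sum_{J<=i} w_J / sum_k w_k
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .network import AttentionNetwork, UndirectedAttentionNetwork

__all__ = [
    "strength",
    "group_strength",
    "outgoing_weight_profile",
    "weighted_degree_centrality",
    "uniformity",
    "cut_size",
    "normalized_cut_size",
    "maximal_cliques",
    "CliqueStats",
    "clique_stats",
    "MetricsReport",
    "compute_metrics",
]


def strength(net: AttentionNetwork, node: str) -> float:
    """Weighted degree: sum of the node's incoming and outgoing edge weights."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    return float(
        net.graph.in_degree(node, weight="weight") + net.graph.out_degree(node, weight="weight")
    )


def group_strength(net: AttentionNetwork, group: Iterable[str], exclude_internal: bool = False) -> float:
    """Summed strength over a group of OOIs.

    By default this is the literal sum of per-node strengths, so an edge
    with both endpoints inside the group contributes twice.  With
    ``exclude_internal=True`` only edges crossing the group boundary count,
    each once.
    """
    group = set(group)
    if not group:
        raise ValueError("group must be non-empty")
    unknown = group - set(net.graph.nodes)
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)}")
    if not exclude_internal:
        return float(sum(strength(net, n) for n in group))
    total = 0.0
    for u, v, data in net.graph.edges(data=True):
        if (u in group) != (v in group):
            total += data["weight"]
    return float(total)


def outgoing_weight_profile(net: AttentionNetwork, node: str) -> List[float]:
    """Ascending-sorted outgoing edge weights of a node (its WDC profile)."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    return sorted(float(d["weight"]) for _, _, d in net.graph.out_edges(node, data=True))


def weighted_degree_centrality(weights: Sequence[float]) -> float:
    """Uniformity index of a node's outgoing edge weights.

    ``weights`` are the node's outgoing edge weights in any order; they are
    sorted ascending internally (required so that profiles from different
    participants are comparable).  With DC = len(weights) and cumulative
    weight fractions Fc(i):

        WDC = 1 + 2 * sum_{i=1}^{DC-1} Fc(i)

    lies in [1, DC]; it equals DC exactly when all weights are equal and
    approaches 1 as the profile concentrates on a single edge.  Invariant
    under rescaling all weights by a positive constant.
    """
    w = np.sort(np.asarray(list(weights), dtype=float))
    if w.size == 0:
        raise ValueError("weight profile must contain at least one outgoing edge")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("edge weights must be positive and finite")
    fc = np.cumsum(w) / w.sum()
    return float(1.0 + 2.0 * fc[:-1].sum())


def _edge_weights(net) -> np.ndarray:
    return np.asarray([d["weight"] for _, _, d in net.graph.edges(data=True)], dtype=float)


def uniformity(net: AttentionNetwork) -> float:
    """Negated chi-square statistic of all directed edge weights.

    U = -sum_e (w_e - mean)^2 / mean, testing the observed weights against
    a uniform expectation.  U <= 0 always; U = 0 iff every edge carries the
    same weight.  Only edges present in the graph enter — absent OOI pairs
    are not zero-count categories.
    """
    w = _edge_weights(net)
    if w.size == 0:
        raise ValueError("uniformity requires at least one edge")
    return float(-stats.chisquare(w).statistic)


def _check_partition(net, set_s: Set[str], set_t: Set[str]) -> Tuple[set, set]:
    s, t = set(set_s), set(set_t)
    if not s or not t:
        raise ValueError("both partition sets must be non-empty")
    if s & t:
        raise ValueError(f"partition sets overlap: {sorted(s & t)}")
    unknown = (s | t) - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"partition references unknown nodes: {sorted(unknown)}")
    return s, t


def cut_size(net: AttentionNetwork, set_s: Iterable[str], set_t: Iterable[str]) -> float:
    """Total weight of edges crossing the partition, both directions counted.

    Answers "how often did gaze transition between these two sets of OOIs",
    so S->T and T->S edges both contribute.
    """
    s, t = _check_partition(net, set_s, set_t)
    return float(nx.cut_size(net.graph, s, t, weight="weight"))


def normalized_cut_size(net: AttentionNetwork, set_s: Iterable[str], set_t: Iterable[str]) -> float:
    """Cut size divided by the total edge weight of the whole network.

    Note this is *not* the volume-based normalized cut of spectral graph
    partitioning (as in ``networkx.normalized_cut_size``); it expresses the
    crossing traffic as a fraction of all gaze transitions, in [0, 1].
    """
    total = net.total_weight
    if total == 0:
        raise ValueError("normalized cut size undefined on an edgeless network")
    return cut_size(net, set_s, set_t) / total


def maximal_cliques(unet: UndirectedAttentionNetwork) -> List[Tuple[str, ...]]:
    """All maximal cliques over positive-weight edges, canonically sorted.

    Requires the undirected conversion; passing a directed network raises.
    Isolated nodes are maximal cliques of size one by definition and are
    included.  Each clique is a sorted tuple; the list is sorted
    lexicographically for deterministic output.
    """
    if isinstance(unet, AttentionNetwork) or (
        hasattr(unet, "graph") and isinstance(unet.graph, nx.DiGraph)
    ):
        raise TypeError(
            "maximal cliques require an undirected network; apply to_undirected() first"
        )
    g = nx.Graph()
    g.add_nodes_from(unet.graph.nodes)
    g.add_edges_from(
        (u, v) for u, v, d in unet.graph.edges(data=True) if d.get("weight", 0) > 0
    )
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


@dataclass(frozen=True)
class CliqueStats:
    """Clique summary, reported both over all maximal cliques and over the
    non-trivial (size >= 2) ones, since singleton cliques are a definitional
    edge case."""

    count: int
    average_size: float
    count_nontrivial: int
    average_size_nontrivial: float
    cliques: Tuple[Tuple[str, ...], ...]


def clique_stats(unet: UndirectedAttentionNetwork) -> CliqueStats:
    cliques = maximal_cliques(unet)
    sizes = [len(c) for c in cliques]
    big = [s for s in sizes if s >= 2]
    return CliqueStats(
        count=len(sizes),
        average_size=float(np.mean(sizes)) if sizes else 0.0,
        count_nontrivial=len(big),
        average_size_nontrivial=float(np.mean(big)) if big else 0.0,
        cliques=tuple(cliques),
    )


@dataclass
class MetricsReport:
    """All structural variables for one network, with the parameters used."""

    participant_id: str
    parameters: dict
    node_strength: dict
    group_strengths: dict
    wdc: dict
    uniformity: Optional[float]
    cuts: dict
    clique_count: int
    average_clique_size: float
    clique_count_nontrivial: int
    average_clique_size_nontrivial: float
    cliques: list

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=str) + "\n"
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def compute_metrics(
    net: AttentionNetwork,
    groups: Optional[dict] = None,
    partitions: Optional[dict] = None,
    exclude_internal: bool = False,
) -> MetricsReport:
    """Compute the full structural-variable report for one network.

    ``groups`` maps group names to OOI name lists for group strength;
    ``partitions`` maps partition names to (S, T) pairs of OOI name lists
    for cut sizes.  Per-node WDC is reported for every node with at least
    one outgoing edge; uniformity is None for edgeless networks.
    """
    nodes = sorted(net.graph.nodes)
    node_strength = {n: strength(net, n) for n in nodes}
    wdc = {}
    for n in nodes:
        profile = outgoing_weight_profile(net, n)
        if profile:
            wdc[n] = weighted_degree_centrality(profile)
    u = uniformity(net) if net.graph.number_of_edges() > 0 else None
    group_strengths = {}
    for gname, members in (groups or {}).items():
        group_strengths[gname] = group_strength(net, members, exclude_internal=exclude_internal)
    cuts = {}
    for pname, (s, t) in (partitions or {}).items():
        cuts[pname] = {
            "cut_size": cut_size(net, s, t),
            "normalized_cut_size": normalized_cut_size(net, s, t),
        }
    cs = clique_stats(to_undirected_safe(net))
    return MetricsReport(
        participant_id=net.participant_id,
        parameters={
            "nodes": nodes,
            "groups": {k: sorted(v) for k, v in (groups or {}).items()},
            "partitions": {k: [sorted(s), sorted(t)] for k, (s, t) in (partitions or {}).items()},
            "exclude_internal_group_edges": exclude_internal,
            **net.metadata,
        },
        node_strength=node_strength,
        group_strengths=group_strengths,
        wdc=wdc,
        uniformity=u,
        cuts=cuts,
        clique_count=cs.count,
        average_clique_size=cs.average_size,
        clique_count_nontrivial=cs.count_nontrivial,
        average_clique_size_nontrivial=cs.average_size_nontrivial,
        cliques=[list(c) for c in cs.cliques],
    )


def to_undirected_safe(net: AttentionNetwork) -> UndirectedAttentionNetwork:
    from .network import to_undirected

    return to_undirected(net)
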