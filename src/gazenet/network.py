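"""Weighted attention networks built from gaze-transition tables.

One directed graph per participant per session: nodes are the analysis
OOIs, an edge (u, v) carries the count of gaze transitions u -> v.  The
undirected conversion sums reciprocal edge weights, so undirected strength
equals total transition involvement.  Serialization is a plain edge-list
CSV plus a JSON metadata sidecar (and optionally GraphML), so networks stay
inspectable and portable across languages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .preprocess import TransitionTable

__all__ = [
    "AttentionNetwork",
    "UndirectedAttentionNetwork",
    "build_network",
    "to_undirected",
    "write_network",
    "read_network",
    "write_graphml",
]


def _check_weights(graph) -> None:
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        w = data.get("weight")
        if w is None or w <= 0:
            raise ValueError(f"edge {u!r}->{v!r} has non-positive weight {w!r}")


@dataclass
class AttentionNetwork:
    """Directed, weighted gaze-transition graph for one participant."""

    participant_id: str
    graph: nx.DiGraph
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.graph, nx.DiGraph) or isinstance(self.graph, nx.MultiDiGraph):
            raise TypeError("attention network requires a DiGraph")
        _check_weights(self.graph)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def edge_weights(self) -> dict:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


@dataclass
class UndirectedAttentionNetwork:
    """Undirected view: weight(u-v) = weight(u->v) + weight(v->u)."""

    participant_id: str
    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.graph, nx.Graph) or isinstance(self.graph, (nx.DiGraph, nx.MultiGraph)):
            raise TypeError("undirected attention network requires a Graph")
        _check_weights(self.graph)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def build_network(table: TransitionTable, nodes: Optional[Iterable[str]] = None) -> AttentionNetwork:
    """Count transitions per (source, target) pair into a weighted DiGraph.

    The node set is the union of a supplied roster and all transition
    endpoints, so never-gazed OOIs appear as isolated nodes and structural
    variables stay comparable across participants.
    """
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    counts = table.transitions.groupby(["source", "target"]).size()
    for (src, tgt), n in counts.items():
        g.add_edge(src, tgt, weight=int(n))
    meta = {
        "max_duration_ms": table.max_duration_ms,
        "n_transitions": int(len(table)),
        "n_excluded_duration": int(table.n_excluded_duration),
        "n_dropped_samples": int(table.n_dropped_samples),
    }
    return AttentionNetwork(participant_id=table.participant_id, graph=g, metadata=meta)


def to_undirected(net: AttentionNetwork) -> UndirectedAttentionNetwork:
    """Merge reciprocal directed edges by summing their weights."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, data in net.graph.edges(data=True):
        if g.has_edge(u, v):
            g[u][v]["weight"] += data["weight"]
        else:
            g.add_edge(u, v, weight=data["weight"])
    return UndirectedAttentionNetwork(
        participant_id=net.participant_id, graph=g, metadata=dict(net.metadata)
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_network(net: AttentionNetwork, path) -> None:
    """Write an edge-list CSV (source,target,weight) plus a JSON sidecar.

    Edges are sorted by (source, target) for byte-stable output; the
    sidecar records participant, the full node roster (including isolated
    nodes) and metadata, making the round trip lossless.
    """
    path = Path(path)
    lines = ["source,target,weight"]
    for u, v in sorted(net.graph.edges()):
        lines.append(f"{u},{v},{net.graph[u][v]['weight']}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "participant_id": net.participant_id,
        "nodes": sorted(net.graph.nodes),
        "metadata": net.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_network(path) -> AttentionNetwork:
    """Read an edge-list CSV written by :func:`write_network`.

    Malformed rows (wrong arity, non-positive or non-integer weight,
    duplicate edges) are rejected with the offending line number.
    """
    path = Path(path)
    g = nx.DiGraph()
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "source,target,weight":
        raise ValueError(f"{path}:1: expected header 'source,target,weight'")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        u, v, w_str = (p.strip() for p in parts)
        try:
            w = int(w_str)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: weight {w_str!r} is not an integer") from exc
        if w <= 0:
            raise ValueError(f"{path}:{lineno}: weight must be positive, got {w}")
        if u == v:
            raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
        if g.has_edge(u, v):
            raise ValueError(f"{path}:{lineno}: duplicate edge {u!r}->{v!r}")
        g.add_edge(u, v, weight=w)

    participant_id, metadata = "", {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        participant_id = info.get("participant_id", "")
        metadata = info.get("metadata", {})
        g.add_nodes_from(info.get("nodes", []))
    return AttentionNetwork(participant_id=participant_id, graph=g, metadata=metadata)


def write_graphml(net, path) -> None:
    """Export the graph (directed or undirected) as GraphML with weights."""
    g = net.graph.copy()
    g.graph["participant_id"] = net.participant_id
    for k, v in net.metadata.items():
        if v is not None:
            g.graph[str(k)] = v
    nx.write_graphml(g, path)
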