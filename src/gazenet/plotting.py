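"""Network visualization: top-down view of a session's attention graph."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .network import AttentionNetwork, UndirectedAttentionNetwork
from .scene import Scene

__all__ = ["plot_network"]


def plot_network(
    net,
    scene: Optional[Scene] = None,
    path=None,
    seed: int = 0,
    max_edge_width: float = 8.0,
    ax=None,
):
    """Draw the attention network with edge widths proportional to weight.

    Nodes sit at their scene positions projected top-down (world x right,
    y up on the page) when a scene provides them; otherwise, and for nodes
    missing from the scene, a deterministic spring layout fills in.
    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    if not isinstance(net, (AttentionNetwork, UndirectedAttentionNetwork)):
        raise TypeError("plot_network expects an attention network")
    g = net.graph
    pos = {}
    if scene is not None:
        names = set(scene.names)
        for node in g.nodes:
            if node in names:
                c = scene[node].center
                pos[node] = (float(c[0]), float(c[1]))
    missing = [n for n in g.nodes if n not in pos]
    if missing:
        fallback = nx.spring_layout(g, seed=seed)
        for n in missing:
            pos[n] = tuple(fallback[n])

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    wmax = max(weights) if weights else 1.0
    widths = [max_edge_width * w / wmax for w in weights]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#4878a8", node_size=600)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8, font_color="white")
    nx.draw_networkx_edges(
        g, pos, ax=ax, width=widths, edge_color="#c05a28",
        arrows=g.is_directed(), connectionstyle="arc3,rad=0.08" if g.is_directed() else None,
    )
    ax.set_title(f"attention network: {net.participant_id}" if net.participant_id else "attention network")
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        ax.figure.savefig(Path(path), bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
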