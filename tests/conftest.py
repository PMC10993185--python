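"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gazenet import (
    OOI,
    AttentionNetwork,
    Box,
    Ray,
    Scene,
    Sphere,
    TransitionTable,
)

# ---------------------------------------------------------------------------
# independent geometric oracle: face-plane box intersection + polynomial-root
# sphere intersection, then an explicit minimum over all collidable objects
# ---------------------------------------------------------------------------


def oracle_sphere_distance(origin, direction, center, radius):
    """Sphere hit distance via polynomial root finding (numpy.roots)."""
    oc = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    roots = np.roots([d @ d, 2 * (oc @ d), oc @ oc - radius**2])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and r.real > 1e-12]
    return min(real) if real else None


def oracle_box_distance(origin, direction, lo, hi):
    """Box hit distance by testing the ray against each of the 6 face planes."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    ts = []
    for axis in range(3):
        for plane in (lo[axis], hi[axis]):
            if abs(direction[axis]) < 1e-15:
                continue
            t = (plane - origin[axis]) / direction[axis]
            if t <= 1e-12:
                continue
            p = origin + t * direction
            others = [a for a in range(3) if a != axis]
            if all(lo[a] - 1e-9 <= p[a] <= hi[a] + 1e-9 for a in others):
                ts.append(t)
    return min(ts) if ts else None


def oracle_first_hit(ray: Ray, scene: Scene):
    """(name, distance) of the nearest collidable object, or None."""
    best = None
    for ooi in scene.oois:
        if not ooi.collidable:
            continue
        if isinstance(ooi.shape, Sphere):
            t = oracle_sphere_distance(ray.origin, ray.direction, ooi.shape.center, ooi.shape.radius)
        else:
            t = oracle_box_distance(ray.origin, ray.direction, ooi.shape.min_corner, ooi.shape.max_corner)
        if t is None or t > ray.length_k:
            continue
        if best is None or t < best[1]:
            best = (ooi.name, t)
    return best


def random_scene(rng: np.random.Generator, max_objects: int = 10) -> Scene:
    """Random scene of spheres and boxes scattered around the origin."""
    n = int(rng.integers(1, max_objects + 1))
    oois = []
    for i in range(n):
        center = rng.uniform(-50, 50, size=3)
        if rng.random() < 0.5:
            shape = Sphere(center=center, radius=float(rng.uniform(0.5, 8.0)))
        else:
            half = rng.uniform(0.5, 8.0, size=3)
            shape = Box(min_corner=center - half, max_corner=center + half)
        oois.append(OOI(f"obj{i}", shape, collidable=bool(rng.random() < 0.9)))
    return Scene(oois)


# ---------------------------------------------------------------------------
# independent clique oracle: exhaustive subset enumeration
# ---------------------------------------------------------------------------


def brute_force_maximal_cliques(graph: nx.Graph):
    """All maximal cliques by checking every node subset (n <= ~10)."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    return sorted(tuple(sorted(c)) for c in maximal)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_network(edges, nodes=(), participant="p1") -> AttentionNetwork:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return AttentionNetwork(participant_id=participant, graph=g)


def make_table(rows, participant="p1", **kwargs) -> TransitionTable:
    df = pd.DataFrame(rows, columns=["t_start_ms", "duration_ms", "source", "target"])
    return TransitionTable(participant_id=participant, transitions=df, **kwargs)


@pytest.fixture
def toy_network() -> AttentionNetwork:
    """A->B 2, B->A 1, B->C 1: the smallest network exercising all metrics."""
    return make_network([("A", "B", 2), ("B", "A", 1), ("B", "C", 1)])


@pytest.fixture
def two_object_scene() -> Scene:
    return Scene(
        [
            OOI("board", Sphere(center=(10, 0, 0), radius=1)),
            OOI("wall", Box(min_corner=(20, -1, -1), max_corner=(22, 1, 1))),
        ]
    )
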