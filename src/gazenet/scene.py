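"""Scenes of gaze-target objects (OOIs) and analytic first-hit ray casting.

A scene is an ordered list of named objects of interest — spheres or
axis-aligned boxes in world coordinates (unreal units) — standing in for a
rendered virtual environment.  :func:`first_hit` replaces an engine line
trace: it returns the nearest collidable object intersected by a gaze ray,
with impact point and distance, or a miss.  Non-collidable objects are
transparent to the ray (the software analogue of disabling a collider).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .geometry import Ray, _as_vec3

__all__ = ["Sphere", "Box", "OOI", "Scene", "HitRecord", "first_hit", "intersect_distance"]

_EPS = 1e-12


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center, "sphere center"))
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    def to_dict(self) -> dict:
        return {"shape": "sphere", "center": [float(c) for c in self.center], "radius": float(self.radius)}


@dataclass(frozen=True)
class Box:
    """Axis-aligned box spanning min_corner..max_corner (componentwise)."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = _as_vec3(self.min_corner, "box min corner")
        hi = _as_vec3(self.max_corner, "box max corner")
        if not np.all(lo < hi):
            raise ValueError(f"box min corner must be strictly below max corner: {lo} vs {hi}")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min_corner + self.max_corner)

    def to_dict(self) -> dict:
        return {
            "shape": "box",
            "min": [float(c) for c in self.min_corner],
            "max": [float(c) for c in self.max_corner],
        }


Shape = Union[Sphere, Box]


@dataclass(frozen=True)
class OOI:
    """A named object of interest — a potential gaze target."""

    name: str
    shape: Shape
    collidable: bool = True

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("OOI name must be a non-empty string")
        if not isinstance(self.shape, (Sphere, Box)):
            raise TypeError(f"unsupported OOI shape: {type(self.shape).__name__}")

    @property
    def center(self) -> np.ndarray:
        return self.shape.center


@dataclass(frozen=True)
class Scene:
    """Ordered collection of OOIs; order breaks exact first-hit ties.

    ``analysis_oois`` optionally marks the subset used as transition
    endpoints downstream; other objects are merely trackable occluders.
    """

    oois: tuple
    analysis_oois: Optional[tuple] = None

    def __init__(self, oois: Sequence[OOI], analysis_oois: Optional[Sequence[str]] = None):
        oois = tuple(oois)
        names = [o.name for o in oois]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate OOI names in scene: {sorted(dupes)}")
        if analysis_oois is not None:
            analysis_oois = tuple(analysis_oois)
            unknown = set(analysis_oois) - set(names)
            if unknown:
                raise ValueError(f"analysis OOIs not present in scene: {sorted(unknown)}")
        object.__setattr__(self, "oois", oois)
        object.__setattr__(self, "analysis_oois", analysis_oois)

    @property
    def names(self) -> list:
        return [o.name for o in self.oois]

    @property
    def analysis_names(self) -> list:
        """Names used as transition endpoints (all OOIs unless restricted)."""
        if self.analysis_oois is not None:
            return list(self.analysis_oois)
        return self.names

    def __getitem__(self, name: str) -> OOI:
        for o in self.oois:
            if o.name == name:
                return o
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = {"oois": [{"name": o.name, **o.shape.to_dict(), "collidable": o.collidable} for o in self.oois]}
        if self.analysis_oois is not None:
            d["analysis_oois"] = list(self.analysis_oois)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        oois = []
        for entry in d.get("oois", []):
            entry = dict(entry)
            name = entry.pop("name")
            kind = entry.pop("shape")
            collidable = bool(entry.pop("collidable", True))
            if kind == "sphere":
                shape: Shape = Sphere(center=entry["center"], radius=entry["radius"])
            elif kind == "box":
                shape = Box(min_corner=entry["min"], max_corner=entry["max"])
            else:
                raise ValueError(f"unknown OOI shape {kind!r} for {name!r}")
            oois.append(OOI(name=name, shape=shape, collidable=collidable))
        return cls(oois, analysis_oois=d.get("analysis_oois"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "Scene":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"scene file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"scene file {path} does not contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class HitRecord:
    """Outcome of a gaze-ray cast: target name, impact point, distance (uu)."""

    hit: bool
    target_name: Optional[str] = None
    impact_point: Optional[np.ndarray] = None
    distance: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hit:
            if any(v is not None for v in (self.target_name, self.impact_point, self.distance)):
                raise ValueError("miss records carry no target, point, or distance")
        else:
            if self.target_name is None or self.impact_point is None or self.distance is None:
                raise ValueError("hit records require target, impact point, and distance")
            object.__setattr__(self, "impact_point", _as_vec3(self.impact_point, "impact point"))
            if self.distance < 0:
                raise ValueError("hit distance must be non-negative")


def _intersect_sphere(ray: Ray, s: Sphere) -> Optional[float]:
    oc = ray.origin - s.center
    b = float(oc @ ray.direction)
    c = float(oc @ oc) - s.radius * s.radius
    disc = b * b - c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    for t in (-b - sq, -b + sq):
        if t > _EPS:
            return t
    return None


def _intersect_box(ray: Ray, box: Box) -> Optional[float]:
    # slab method; origin inside the box hits the exit face
    tmin, tmax = -math.inf, math.inf
    for axis in range(3):
        o, d = ray.origin[axis], ray.direction[axis]
        lo, hi = box.min_corner[axis], box.max_corner[axis]
        if abs(d) < _EPS:
            if o < lo or o > hi:
                return None
            continue
        t1, t2 = (lo - o) / d, (hi - o) / d
        if t1 > t2:
            t1, t2 = t2, t1
        tmin, tmax = max(tmin, t1), min(tmax, t2)
        if tmin > tmax:
            return None
    if tmax < _EPS:
        return None
    return tmin if tmin > _EPS else tmax


def intersect_distance(ray: Ray, shape: Shape) -> Optional[float]:
    """Smallest positive distance along the ray to the shape, or None.

    Ignores the ray's length bound; callers compare against ``length_k``.
    """
    if isinstance(shape, Sphere):
        return _intersect_sphere(ray, shape)
    if isinstance(shape, Box):
        return _intersect_box(ray, shape)
    raise TypeError(f"unsupported shape: {type(shape).__name__}")


def first_hit(ray: Ray, scene: Scene) -> HitRecord:
    """First collidable OOI hit by the gaze ray, or a miss record.

    Among collidable objects intersected within the segment
    ``[origin, origin + direction * length_k]`` the one at minimal positive
    distance wins; exact ties go to the earlier object in scene order.
    """
    best: Optional[tuple] = None
    for ooi in scene.oois:
        if not ooi.collidable:
            continue
        t = intersect_distance(ray, ooi.shape)
        if t is None or t > ray.length_k:
            continue
        if best is None or t < best[0]:
            best = (t, ooi)
    if best is None:
        return HitRecord(hit=False)
    t, ooi = best
    return HitRecord(
        hit=True,
        target_name=ooi.name,
        impact_point=ray.origin + ray.direction * t,
        distance=float(t),
    )
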