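"""Gaze geometry: local eye-tracker directions to global gaze rays.

Head-mounted eye trackers report gaze in a *local* right-handed frame fixed
to the headset (z forward, x left, y up — the Tobii convention), while scene
objects live in a *world* left-handed frame (x forward, y right, z up — the
Unreal convention, 1 unreal unit (uu) = 1 cm).  The bridge is a pair of
rotation angles:

    yaw   = -arccos(z / sqrt(x^2 + z^2)) * 180/pi * sgn(x)
    pitch =  arccos(sqrt(x^2 + z^2) / |g|) * 180/pi * sgn(y)

applied to the head's forward vector — yaw about the head's up axis, then
pitch about the post-yaw right axis.  The leading minus sign and the signum
carry the handedness change, so for an identity head pose the rotated
forward vector equals the direct frame conversion (x, y, z) -> (z, -x, y).

The global gaze ray starts at the head position and extends ``length_k``
unreal units along the rotated forward direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_RAY_LENGTH_UU",
    "GazeAngles",
    "HeadPose",
    "Ray",
    "gaze_angles",
    "global_gaze_ray",
    "local_to_world",
    "rotate_forward",
    "world_to_local",
]

#: Default gaze-ray length in unreal units (250 m); rays stop at the first
#: hit, so the exact value only matters as an upper bound on gaze distance.
DEFAULT_RAY_LENGTH_UU = 25000.0


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite components: {arr}")
    return arr


def _sgn(x: float) -> float:
    """Signum with sgn(0) := +1, the convention used for the gaze angles."""
    return -1.0 if x < 0 else 1.0


@dataclass(frozen=True)
class GazeAngles:
    """Yaw/pitch rotation (degrees) taking head-forward to the gaze direction."""

    yaw_deg: float
    pitch_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.yaw_deg) and math.isfinite(self.pitch_deg)):
            raise ValueError("gaze angles must be finite")
        if not -180.0 <= self.yaw_deg <= 180.0:
            raise ValueError(f"yaw {self.yaw_deg} outside [-180, 180] degrees")
        if not -90.0 <= self.pitch_deg <= 90.0:
            raise ValueError(f"pitch {self.pitch_deg} outside [-90, 90] degrees")


@dataclass(frozen=True)
class HeadPose:
    """Head position (uu) and orientation in the world frame.

    Orientation is stored as an orthonormal forward/right/up triad.  Use
    :meth:`identity`, :meth:`from_quaternion` or :meth:`from_yaw_pitch_roll`
    to construct one.
    """

    position: np.ndarray
    forward: np.ndarray
    right: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec3(self.position, "position"))
        triad = []
        for name in ("forward", "right", "up"):
            v = _as_vec3(getattr(self, name), name)
            n = float(np.linalg.norm(v))
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"head {name} vector not normalized (norm {n})")
            triad.append(v)
            object.__setattr__(self, name, v)
        f, r, u = triad
        gram = np.abs([f @ r, f @ u, r @ u])
        if np.any(gram > 1e-9):
            raise ValueError("head orientation triad is not orthonormal")

    @classmethod
    def identity(cls, position=(0.0, 0.0, 0.0)) -> "HeadPose":
        return cls(
            position=np.asarray(position, dtype=float),
            forward=np.array([1.0, 0.0, 0.0]),
            right=np.array([0.0, 1.0, 0.0]),
            up=np.array([0.0, 0.0, 1.0]),
        )

    @classmethod
    def from_quaternion(cls, position, q) -> "HeadPose":
        """Build a pose from a unit quaternion (w, x, y, z).

        The quaternion rotates the world basis vectors; the image of
        (1,0,0)/(0,1,0)/(0,0,1) becomes the forward/right/up triad.
        """
        q = np.asarray(q, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must be (w, x, y, z)")
        n = float(np.linalg.norm(q))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"quaternion not normalized (norm {n})")
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        return cls(
            position=np.asarray(position, dtype=float),
            forward=rot[:, 0],
            right=rot[:, 1],
            up=rot[:, 2],
        )

    @classmethod
    def from_yaw_pitch_roll(cls, position, yaw_deg: float = 0.0, pitch_deg: float = 0.0, roll_deg: float = 0.0) -> "HeadPose":
        """Intrinsic yaw (about up, forward-toward-right positive), then pitch
        (about the new right, forward-toward-up positive), then roll (about
        the new forward, up-toward-right positive)."""
        f = np.array([1.0, 0.0, 0.0])
        r = np.array([0.0, 1.0, 0.0])
        u = np.array([0.0, 0.0, 1.0])
        cy, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
        f, r = cy * f + sy * r, -sy * f + cy * r
        cp, sp = math.cos(math.radians(pitch_deg)), math.sin(math.radians(pitch_deg))
        f, u = cp * f + sp * u, -sp * f + cp * u
        cr, sr = math.cos(math.radians(roll_deg)), math.sin(math.radians(roll_deg))
        u, r = cr * u + sr * r, -sr * u + cr * r
        return cls(position=np.asarray(position, dtype=float), forward=f, right=r, up=u)

    def quaternion(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z) whose rotation matrix has columns
        forward/right/up.  Inverse of :meth:`from_quaternion`."""
        rot = np.column_stack([self.forward, self.right, self.up])
        tr = float(np.trace(rot))
        if tr > 0:
            s = math.sqrt(tr + 1.0) * 2
            w = 0.25 * s
            x = (rot[2, 1] - rot[1, 2]) / s
            y = (rot[0, 2] - rot[2, 0]) / s
            z = (rot[1, 0] - rot[0, 1]) / s
        else:
            i = int(np.argmax(np.diag(rot)))
            j, k = (i + 1) % 3, (i + 2) % 3
            s = math.sqrt(rot[i, i] - rot[j, j] - rot[k, k] + 1.0) * 2
            vals = [0.0, 0.0, 0.0]
            vals[i] = 0.25 * s
            vals[j] = (rot[j, i] + rot[i, j]) / s
            vals[k] = (rot[k, i] + rot[i, k]) / s
            w = (rot[k, j] - rot[j, k]) / s
            x, y, z = vals
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q / np.linalg.norm(q)


@dataclass(frozen=True)
class Ray:
    """A gaze ray: origin + direction * t for t in (0, length_k], all in uu."""

    origin: np.ndarray
    direction: np.ndarray
    length_k: float = DEFAULT_RAY_LENGTH_UU

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_vec3(self.origin, "ray origin"))
        d = _as_vec3(self.direction, "ray direction")
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"ray direction not normalized (norm {n})")
        object.__setattr__(self, "direction", d / n)
        if not (math.isfinite(self.length_k) and self.length_k > 0):
            raise ValueError(f"ray length k must be positive, got {self.length_k}")

    @property
    def endpoint(self) -> np.ndarray:
        return self.origin + self.direction * self.length_k


def gaze_angles(local_gaze) -> GazeAngles:
    """Yaw and pitch (degrees) of a normalized local gaze direction.

    ``local_gaze`` is in the eye tracker's right-handed frame (z forward,
    x left, y up).  Yaw is negative for leftward gaze (x > 0 locally),
    pitch positive for upward gaze; both are 0 along local forward (0,0,1).
    Degenerate vertical gaze (x = z = 0) gets yaw := 0.
    """
    g = _as_vec3(local_gaze, "local gaze")
    norm = float(np.linalg.norm(g))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"local gaze must be normalized, got norm {norm}")
    x, y, z = g
    flat = math.hypot(x, z)
    if flat == 0.0:
        yaw = 0.0
    else:
        yaw = -math.degrees(math.acos(min(1.0, max(-1.0, z / flat)))) * _sgn(x)
    pitch = math.degrees(math.acos(min(1.0, max(-1.0, flat / norm)))) * _sgn(y)
    return GazeAngles(yaw_deg=yaw, pitch_deg=pitch)


def rotate_forward(head: HeadPose, angles: GazeAngles) -> np.ndarray:
    """Rotate the head's forward vector by gaze yaw then pitch.

    Yaw rotates about the head's up axis (forward-toward-right positive),
    pitch about the post-yaw right axis (forward-toward-up positive).  In
    the head basis this is the closed form
    ``cosP*cosY*f + cosP*sinY*r + sinP*u``; the result is normalized.
    """
    y = math.radians(angles.yaw_deg)
    p = math.radians(angles.pitch_deg)
    v = (
        math.cos(p) * math.cos(y) * head.forward
        + math.cos(p) * math.sin(y) * head.right
        + math.sin(p) * head.up
    )
    return v / np.linalg.norm(v)


def global_gaze_ray(head: HeadPose, f_rotated, k: float = DEFAULT_RAY_LENGTH_UU) -> Ray:
    """Gaze ray from the head position along the rotated forward direction.

    The endpoint is ``head.position + f_rotated * k`` (uu).  ``k`` must be
    positive; it bounds the gaze distance and is otherwise inert because
    ray casting stops at the first hit.
    """
    if not (math.isfinite(k) and k > 0):
        raise ValueError(f"gaze vector length k must be positive, got {k}")
    return Ray(origin=head.position, direction=f_rotated, length_k=float(k))


def local_to_world(local_gaze, head: HeadPose) -> np.ndarray:
    """Convert a local (Tobii-frame) direction to a world direction.

    Equivalent to ``rotate_forward(head, gaze_angles(g))`` but exact:
    the local (x, y, z) maps to z*forward - x*right + y*up.
    """
    g = _as_vec3(local_gaze, "local gaze")
    n = float(np.linalg.norm(g))
    if n == 0:
        raise ValueError("local gaze direction is the zero vector")
    x, y, z = g / n
    return z * head.forward - x * head.right + y * head.up


def world_to_local(world_dir, head: HeadPose) -> np.ndarray:
    """Inverse of :func:`local_to_world`: world direction to the Tobii frame."""
    d = _as_vec3(world_dir, "world direction")
    n = float(np.linalg.norm(d))
    if n == 0:
        raise ValueError("world direction is the zero vector")
    d = d / n
    a, b, c = d @ head.forward, d @ head.right, d @ head.up
    return np.array([-b, c, a])
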