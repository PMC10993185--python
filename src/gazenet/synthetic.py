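"""Synthetic VR-classroom eye-tracking sessions with known ground truth.

A session is driven by a Markov attention process over the scene's OOIs:
the chain picks which object is attended next (zero diagonal — the chain
only moves), a truncated-normal dwell time says for how long, and the
logger emits one frame every 25 ms (40 frames per second by default, the
sampling model of a consumer HMD eye tracker; a 15-minute session yields
36,000 rows).  Per frame the direction from the head to the attended
object's center is perturbed by angular gaze noise, converted into the
eye tracker's local frame given the simulated head pose, and written with
pupil diameters.  A configurable fraction of frames is marked invalid by
setting the pupil fields to the -1 placeholder (the target geometry is
still logged, as a real gaze-ray pipeline reports a target whenever head
tracking is valid).

The generator emulates *where* gaze lands and *when* it moves, not how:
there are no saccade kinematics, no smooth pursuit, and dwell times are
not claimed to match human dwell distributions.  Its value is that the
true attention sequence and transition counts are known exactly, so every
downstream stage can be verified end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .geometry import HeadPose
from .scene import OOI, Box, Scene, Sphere

__all__ = [
    "MarkovAttentionModel",
    "SessionConfig",
    "GroundTruth",
    "sample_attention_sequence",
    "synthesize_session",
    "classroom_scene",
    "classroom_model",
    "separated_scene",
    "uniform_model",
]

DEFAULT_FPS = 40.0
DEFAULT_EYE_HEIGHT_UU = 120.0  # seated eye height, cm


@dataclass(frozen=True)
class MarkovAttentionModel:
    """First-order Markov chain over OOIs with per-state dwell parameters.

    ``transition_probs`` is row-stochastic with a zero diagonal: attention
    always moves to a *different* object.  Dwell times are truncated
    normal, bounded below by ``min_dwell_ms`` (one frame by default) so a
    dwell is always observable.
    """

    states: Tuple[str, ...]
    transition_probs: np.ndarray
    dwell_mean_ms: np.ndarray
    dwell_sd_ms: np.ndarray
    min_dwell_ms: float = 25.0

    def __init__(
        self,
        states: Sequence[str],
        transition_probs,
        dwell_mean_ms: Union[float, Sequence[float]] = 800.0,
        dwell_sd_ms: Union[float, Sequence[float]] = 400.0,
        min_dwell_ms: float = 25.0,
    ):
        states = tuple(states)
        if len(states) < 2:
            raise ValueError("a Markov attention model needs at least two states")
        if len(set(states)) != len(states):
            raise ValueError("duplicate state names")
        p = np.asarray(transition_probs, dtype=float)
        n = len(states)
        if p.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}, got {p.shape}")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("transition probabilities must be finite and non-negative")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.abs(np.diag(p)) > 0):
            raise ValueError("transition matrix diagonal must be zero (attention must move)")
        mean = np.broadcast_to(np.asarray(dwell_mean_ms, dtype=float), (n,)).copy()
        sd = np.broadcast_to(np.asarray(dwell_sd_ms, dtype=float), (n,)).copy()
        if np.any(mean <= 0) or np.any(sd <= 0):
            raise ValueError("dwell mean and sd must be positive")
        if min_dwell_ms <= 0:
            raise ValueError("min_dwell_ms must be positive")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transition_probs", p)
        object.__setattr__(self, "dwell_mean_ms", mean)
        object.__setattr__(self, "dwell_sd_ms", sd)
        object.__setattr__(self, "min_dwell_ms", float(min_dwell_ms))


def uniform_model(
    states: Sequence[str],
    dwell_mean_ms: float = 800.0,
    dwell_sd_ms: float = 400.0,
) -> MarkovAttentionModel:
    """Equal probability of moving to any other state."""
    n = len(states)
    p = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(p, 0.0)
    return MarkovAttentionModel(states, p, dwell_mean_ms, dwell_sd_ms)


def sample_attention_sequence(
    model: MarkovAttentionModel,
    duration_ms: float,
    seed: Union[int, np.random.Generator] = 0,
) -> List[Tuple[str, float]]:
    """Sample (OOI, dwell_ms) segments covering at least ``duration_ms``.

    The initial state is drawn uniformly; consecutive states always differ.
    The last segment is clipped so that total dwell equals ``duration_ms``
    exactly.  A fixed seed gives an identical sequence on repeat.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(model.states)
    state = int(rng.integers(n))
    segments: List[Tuple[str, float]] = []
    total = 0.0
    while total < duration_ms:
        # truncated normal by rejection; falls back to the bound after a
        # bounded number of tries so pathological parameters cannot hang
        dwell = model.min_dwell_ms
        for _ in range(100):
            d = rng.normal(model.dwell_mean_ms[state], model.dwell_sd_ms[state])
            if d >= model.min_dwell_ms:
                dwell = d
                break
        dwell = min(dwell, duration_ms - total)
        segments.append((model.states[state], dwell))
        total += dwell
        state = int(rng.choice(n, p=model.transition_probs[state]))
    return segments


@dataclass
class GroundTruth:
    """True attention schedule behind a synthetic session.

    ``segments`` has one row per dwell (ooi, t_start_ms, dwell_ms);
    ``transition_counts`` the true source/target/count table implied by the
    segment sequence.
    """

    segments: pd.DataFrame
    transition_counts: pd.DataFrame

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        self.segments.to_csv(prefix.with_name(prefix.name + "_segments.csv"), index=False)
        self.transition_counts.to_csv(
            prefix.with_name(prefix.name + "_true_transitions.csv"), index=False
        )


@dataclass
class SessionConfig:
    """Everything that determines one synthetic session.

    Defaults reproduce the seated-lecture recording model: a 15-minute
    session sampled at 40 frames per second with a fixed head pose,
    1 degree of angular gaze noise and 5% invalid frames.
    """

    scene: Scene
    model: MarkovAttentionModel
    duration_s: float = 900.0
    fps: float = DEFAULT_FPS
    seed: int = 0
    gaze_noise_deg: float = 1.0
    invalid_rate: float = 0.05
    fixed_rate: bool = True
    head_position: Tuple[float, float, float] = (0.0, 0.0, DEFAULT_EYE_HEIGHT_UU)
    head_mode: str = "fixed"  # "fixed" or "follow"
    head_follow_rate: float = 0.05  # per-frame fraction of the yaw gap closed
    participant_id: str = "sim"
    pupil_mean_mm: float = 3.5
    pupil_sd_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.gaze_noise_deg < 0:
            raise ValueError("gaze_noise_deg must be non-negative")
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ValueError("invalid_rate must be in [0, 1)")
        if self.head_mode not in ("fixed", "follow"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        missing = set(self.model.states) - set(self.scene.names)
        if missing:
            raise ValueError(f"model states not in scene: {sorted(missing)}")


def _frame_times(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    dt = 1000.0 / cfg.fps
    duration_ms = cfg.duration_s * 1000.0
    if cfg.fixed_rate:
        n = int(round(cfg.duration_s * cfg.fps))
        return np.arange(n) * dt
    # jittered frame intervals: half the nominal period plus an exponential
    # tail with the same half-period mean, so intervals average dt but vary
    times = []
    t = 0.0
    while t < duration_ms:
        times.append(t)
        t += 0.5 * dt + rng.exponential(0.5 * dt)
    return np.asarray(times)


def _perturb_directions(d: np.ndarray, noise_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt each unit row vector by independent Gaussian angles about two
    orthogonal axes perpendicular to it."""
    if noise_deg == 0:
        return d
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(d), 1))
    near_pole = np.abs(d[:, 2]) > 0.99
    ref[near_pole] = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    a = np.tan(np.radians(rng.normal(0.0, noise_deg, size=(len(d), 2))))
    out = d + a[:, :1] * e1 + a[:, 1:] * e2
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def synthesize_session(config: SessionConfig):
    """Generate one raw gaze log and its ground truth.

    Returns ``(raw, truth)`` where ``raw`` is a frame-per-row DataFrame in
    the dialect the preprocessing stage reads (time_ms; local gaze vector
    gaze_x/y/z in the eye-tracker frame; head position head_x/y/z and
    orientation quaternion head_qw..qz; pupil diameters, -1 when the frame
    is invalid) and ``truth`` carries the dwell segments and true
    transition counts.  Output is a pure function of (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    duration_ms = config.duration_s * 1000.0
    segments = sample_attention_sequence(config.model, duration_ms, rng)
    times = _frame_times(config, rng)
    n = len(times)

    names = [s[0] for s in segments]
    dwells = np.array([s[1] for s in segments])
    starts = np.concatenate([[0.0], np.cumsum(dwells)[:-1]])
    seg_idx = np.minimum(np.searchsorted(starts, times, side="right") - 1, len(segments) - 1)

    centers = {o.name: o.center for o in config.scene.oois}
    head_pos = np.asarray(config.head_position, dtype=float)
    attended = np.array([names[i] for i in seg_idx])
    target_centers = np.stack([centers[nm] for nm in attended])

    world_dirs = target_centers - head_pos
    world_dirs /= np.linalg.norm(world_dirs, axis=1, keepdims=True)
    world_dirs = _perturb_directions(world_dirs, config.gaze_noise_deg, rng)

    if config.head_mode == "fixed":
        poses = [HeadPose.identity(head_pos)] * n
        yaws = np.zeros(n)
    else:
        # head lazily follows the attended object's azimuth
        target_yaw = np.degrees(np.arctan2(target_centers[:, 1] - head_pos[1],
                                           target_centers[:, 0] - head_pos[0]))
        yaws = np.empty(n)
        y = target_yaw[0]
        for i in range(n):
            y += config.head_follow_rate * (target_yaw[i] - y)
            yaws[i] = y
        poses = [HeadPose.from_yaw_pitch_roll(head_pos, yaw_deg=y) for y in yaws]

    # world direction -> local Tobii frame: (-d.r, d.u, d.f)
    local = np.empty_like(world_dirs)
    for i, pose in enumerate(poses):
        d = world_dirs[i]
        local[i] = (-(d @ pose.right), d @ pose.up, d @ pose.forward)

    pupils = rng.normal(config.pupil_mean_mm, config.pupil_sd_mm, size=(n, 2))
    pupils = np.clip(pupils, 0.5, None)
    invalid = rng.random(n) < config.invalid_rate
    pupils[invalid] = -1.0

    quats = np.stack([p.quaternion() for p in poses])
    raw = pd.DataFrame(
        {
            "time_ms": times,
            "gaze_x": local[:, 0],
            "gaze_y": local[:, 1],
            "gaze_z": local[:, 2],
            "head_x": head_pos[0],
            "head_y": head_pos[1],
            "head_z": head_pos[2],
            "head_qw": quats[:, 0],
            "head_qx": quats[:, 1],
            "head_qy": quats[:, 2],
            "head_qz": quats[:, 3],
            "pupil_left_mm": pupils[:, 0],
            "pupil_right_mm": pupils[:, 1],
        }
    )

    seg_df = pd.DataFrame({"ooi": names, "t_start_ms": starts, "dwell_ms": dwells})
    pairs = pd.DataFrame({"source": names[:-1], "target": names[1:]})
    counts = (
        pairs.groupby(["source", "target"]).size().rename("count").reset_index()
        if len(pairs)
        else pd.DataFrame(columns=["source", "target", "count"])
    )
    return raw, GroundTruth(segments=seg_df, transition_counts=counts)


def classroom_scene() -> Scene:
    """A seated VR-classroom: board and teacher up front, four peer
    learners at desks.  Coordinates in uu (cm), viewer near the origin
    facing +x."""
    oois = [
        OOI("board", Box(min_corner=(780, -150, 100), max_corner=(800, 150, 250))),
        OOI("teacher", Sphere(center=(650, 120, 150), radius=40)),
        OOI("peer_front_left", Sphere(center=(450, -150, 120), radius=30)),
        OOI("peer_front_right", Sphere(center=(450, 150, 120), radius=30)),
        OOI("peer_back_left", Sphere(center=(250, -200, 120), radius=30)),
        OOI("peer_back_right", Sphere(center=(250, 200, 120), radius=30)),
    ]
    return Scene(oois)


def classroom_model() -> MarkovAttentionModel:
    """Lecture attention: teacher and board dominate, peers get glances."""
    scene = classroom_scene()
    states = scene.names
    attractiveness = {
        "board": 0.35,
        "teacher": 0.35,
        "peer_front_left": 0.075,
        "peer_front_right": 0.075,
        "peer_back_left": 0.075,
        "peer_back_right": 0.075,
    }
    n = len(states)
    p = np.zeros((n, n))
    for i, s in enumerate(states):
        for j, t in enumerate(states):
            if i != j:
                p[i, j] = attractiveness[t]
        p[i] /= p[i].sum()
    mean = np.array([1200.0 if s in ("board", "teacher") else 600.0 for s in states])
    sd = 0.5 * mean
    return MarkovAttentionModel(states, p, mean, sd)


def separated_scene(n_oois: int = 3, distance_uu: float = 500.0, radius_uu: float = 40.0) -> Scene:
    """``n_oois`` spheres fanned out in azimuth in front of the viewer,
    widely separated so gaze noise essentially never mislabels a target."""
    if n_oois < 2:
        raise ValueError("need at least two OOIs")
    span = min(120.0, 40.0 * (n_oois - 1))
    azimuths = np.linspace(-span / 2, span / 2, n_oois)
    oois = []
    for i, az in enumerate(azimuths):
        c = (
            distance_uu * math.cos(math.radians(az)),
            distance_uu * math.sin(math.radians(az)),
            DEFAULT_EYE_HEIGHT_UU,
        )
        oois.append(OOI(f"ooi_{i}", Sphere(center=c, radius=radius_uu)))
    return Scene(oois)
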