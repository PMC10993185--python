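"""Per-participant processing pipeline with staged file outputs.

Mirrors a staged recording-analysis design: every stage writes its
aggregated, strictly smaller artifact before the next begins (raw frames ->
ray-cast labels -> cleaned samples -> transitions -> network -> metrics),
so any intermediate can be inspected or re-run, and one participant's
failure never aborts the batch.  The run log records row counts in and out
of every stage together with all thresholds used, and the counts satisfy a
conservation audit: raw rows = cleaned + dropped; OOI target changes =
transitions kept + excluded by the duration filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import DEFAULT_RAY_LENGTH_UU, HeadPose, Ray, local_to_world
from .metrics import compute_metrics
from .network import build_network, write_graphml, write_network
from .preprocess import (
    DEFAULT_MAX_DURATION_MS,
    DEFAULT_PLACEHOLDER,
    PUPIL_COLS,
    TARGET_COL,
    clean_samples,
    extract_transitions,
    read_raw_log,
    write_transitions,
)
from .scene import Scene, first_hit

__all__ = ["MISS_LABEL", "PipelineConfig", "raycast_samples", "run_participant", "run_pipeline"]

logger = logging.getLogger("gazenet")

#: Target label for frames whose gaze ray hits no collidable OOI.
MISS_LABEL = "__miss__"

GAZE_COLS = ("gaze_x", "gaze_y", "gaze_z")
HEAD_POS_COLS = ("head_x", "head_y", "head_z")
HEAD_QUAT_COLS = ("head_qw", "head_qx", "head_qy", "head_qz")


def raycast_samples(
    samples: pd.DataFrame,
    scene: Scene,
    ray_length_k: float = DEFAULT_RAY_LENGTH_UU,
) -> pd.DataFrame:
    """Label every frame with its first-hit gaze target.

    Expects local gaze (gaze_x/y/z, eye-tracker frame), head position
    (head_x/y/z, uu) and head orientation quaternion (head_qw..qz).  Adds
    ``gaze_target`` (OOI name or the miss label) and ``gaze_distance_uu``
    (NaN on miss).  Frames whose gaze vector is degenerate (zero norm or
    non-finite) are labelled as misses — cleaning decides their fate.
    """
    needed = [*GAZE_COLS, *HEAD_POS_COLS, *HEAD_QUAT_COLS]
    missing = [c for c in needed if c not in samples.columns]
    if missing:
        raise ValueError(f"raycast requires columns {missing}")
    gaze = samples[list(GAZE_COLS)].to_numpy(dtype=float)
    pos = samples[list(HEAD_POS_COLS)].to_numpy(dtype=float)
    quat = samples[list(HEAD_QUAT_COLS)].to_numpy(dtype=float)

    targets: List[str] = []
    distances: List[float] = []
    pose_cache: dict = {}
    for i in range(len(samples)):
        g = gaze[i]
        norm = float(np.linalg.norm(g))
        if not np.all(np.isfinite(g)) or norm < 1e-9:
            targets.append(MISS_LABEL)
            distances.append(np.nan)
            continue
        key = (tuple(pos[i]), tuple(np.round(quat[i], 12)))
        pose = pose_cache.get(key)
        if pose is None:
            pose = HeadPose.from_quaternion(pos[i], quat[i])
            pose_cache[key] = pose
        direction = local_to_world(g / norm, pose)
        hit = first_hit(Ray(origin=pose.position, direction=direction, length_k=ray_length_k), scene)
        targets.append(hit.target_name if hit.hit else MISS_LABEL)
        distances.append(hit.distance if hit.hit else np.nan)

    out = samples.copy()
    out[TARGET_COL] = targets
    out["gaze_distance_uu"] = distances
    return out


@dataclass
class PipelineConfig:
    """Configuration for one batch run; loadable from YAML/JSON."""

    input_dir: Path
    output_dir: Path
    scene_file: Path
    analysis_oois: Optional[List[str]] = None
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS
    validity_columns: Sequence[str] = PUPIL_COLS
    placeholder: float = DEFAULT_PLACEHOLDER
    ray_length_k: float = DEFAULT_RAY_LENGTH_UU
    groups: dict = field(default_factory=dict)
    partitions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.scene_file = Path(self.scene_file)
        if not self.scene_file.exists():
            raise FileNotFoundError(f"scene file does not exist: {self.scene_file}")
        if not self.input_dir.is_dir():
            raise FileNotFoundError(f"input directory does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"pipeline config {path} must be a mapping")
        partitions = {
            name: (list(st[0]), list(st[1])) for name, st in (data.get("partitions") or {}).items()
        }
        return cls(
            input_dir=data["input_dir"],
            output_dir=data["output_dir"],
            scene_file=data["scene_file"],
            analysis_oois=data.get("analysis_oois"),
            max_duration_ms=float(data.get("max_duration_ms", DEFAULT_MAX_DURATION_MS)),
            validity_columns=tuple(data.get("validity_columns", PUPIL_COLS)),
            placeholder=float(data.get("placeholder", DEFAULT_PLACEHOLDER)),
            ray_length_k=float(data.get("ray_length_k", DEFAULT_RAY_LENGTH_UU)),
            groups={k: list(v) for k, v in (data.get("groups") or {}).items()},
            partitions=partitions,
            seed=int(data.get("seed", 0)),
        )


def run_participant(
    raw_path: Path,
    config: PipelineConfig,
    scene: Scene,
    participant_id: Optional[str] = None,
) -> dict:
    """Run all stages for one raw log; returns the audit summary row."""
    raw_path = Path(raw_path)
    pid = participant_id or raw_path.stem
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    raw = read_raw_log(raw_path)
    n_raw = len(raw)
    logger.info("[%s] raw rows: %d", pid, n_raw)

    if TARGET_COL not in raw.columns:
        raw = raycast_samples(raw, scene, ray_length_k=config.ray_length_k)
        logger.info("[%s] ray cast with k=%g uu", pid, config.ray_length_k)

    clean, n_dropped = clean_samples(
        raw, validity_columns=config.validity_columns, placeholder=config.placeholder
    )
    assert n_raw == len(clean) + n_dropped
    clean_path = outdir / f"{pid}_clean.csv"
    clean.to_csv(clean_path, index=False)
    logger.info("[%s] cleaned rows: %d (dropped %d)", pid, len(clean), n_dropped)

    analysis_oois = config.analysis_oois or scene.analysis_names
    table = extract_transitions(
        clean,
        analysis_oois,
        max_duration_ms=config.max_duration_ms,
        participant_id=pid,
        n_dropped_samples=n_dropped,
    )
    write_transitions(table, outdir / f"{pid}_transitions.csv")
    logger.info(
        "[%s] transitions: %d kept, %d excluded (> %g ms)",
        pid, len(table), table.n_excluded_duration, config.max_duration_ms,
    )

    net = build_network(table, nodes=analysis_oois)
    write_network(net, outdir / f"{pid}_edges.csv")
    write_graphml(net, outdir / f"{pid}_network.graphml")

    report = compute_metrics(net, groups=config.groups, partitions=config.partitions)
    report.to_json(outdir / f"{pid}_metrics.json")

    n_edges = net.graph.number_of_edges()
    if not (n_raw >= len(clean) >= len(table) + table.n_excluded_duration >= n_edges):
        raise AssertionError("stage outputs must shrink monotonically")
    return {
        "participant": pid,
        "n_raw": n_raw,
        "n_clean": len(clean),
        "n_dropped": n_dropped,
        "n_transitions": len(table),
        "n_excluded_duration": table.n_excluded_duration,
        "n_edges": n_edges,
        "total_weight": net.total_weight,
        "status": "ok",
        "error": "",
    }


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Process every ``*.csv`` raw log in the input directory.

    Participants are independent: a failure is recorded in the summary
    (status 'error') and the batch continues.  Re-running with the same
    config and inputs produces byte-identical artifacts.
    """
    scene = Scene.from_yaml(config.scene_file)
    raw_files = sorted(config.input_dir.glob("*.csv"))
    if not raw_files:
        raise FileNotFoundError(f"no raw CSV logs found in {config.input_dir}")
    rows = []
    for raw_path in raw_files:
        try:
            rows.append(run_participant(raw_path, config, scene))
        except Exception as exc:  # noqa: BLE001 — per-participant isolation
            logger.error("[%s] failed: %s", raw_path.stem, exc)
            rows.append(
                {
                    "participant": raw_path.stem,
                    "n_raw": None, "n_clean": None, "n_dropped": None,
                    "n_transitions": None, "n_excluded_duration": None,
                    "n_edges": None, "total_weight": None,
                    "status": "error", "error": str(exc),
                }
            )
    summary = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(config.output_dir / "summary.csv", index=False)
    return summary
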