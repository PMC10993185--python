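"""Cleaning raw gaze logs and aggregating them into transition tables.

A raw log is one row per frame with a millisecond timestamp and a gaze
target label (plus optional pupil diameters and passthrough columns).
Cleaning drops rows whose validity columns carry a missing-data placeholder
(conventionally -1) and reduces the log to the columns the network analysis
needs.  Transition extraction then walks the label sequence restricted to
the analysis OOIs: each change of target becomes one transition, timed from
the last sample on the source to the first sample on the target.
Transitions longer than a maximum duration are excluded — the mechanism
that removes indirect shifts through untracked space.

No fixation or saccade event detection is involved anywhere; transitions
are defined purely on the target-label sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIME_COL",
    "TARGET_COL",
    "PUPIL_COLS",
    "DEFAULT_PLACEHOLDER",
    "DEFAULT_MAX_DURATION_MS",
    "TransitionTable",
    "read_raw_log",
    "write_raw_log",
    "clean_samples",
    "extract_transitions",
    "read_transitions",
    "write_transitions",
]

TIME_COL = "time_ms"
TARGET_COL = "gaze_target"
PUPIL_COLS = ("pupil_left_mm", "pupil_right_mm")

#: Value encoding a missing measurement (eye tracker convention).
DEFAULT_PLACEHOLDER = -1.0

#: Default upper bound on transition duration (ms): a generous allowance
#: for one saccade plus a blink; longer gaps are indirect shifts.
DEFAULT_MAX_DURATION_MS = 1000.0

TRANSITION_COLS = ["t_start_ms", "duration_ms", "source", "target"]


@dataclass
class TransitionTable:
    """Per-participant gaze transitions plus bookkeeping counts.

    ``transitions`` has columns t_start_ms, duration_ms, source, target,
    ordered by t_start_ms.  ``n_excluded_duration`` counts target changes
    dropped by the max-duration filter; ``n_dropped_samples`` carries the
    cleaning drop count when known.
    """

    participant_id: str
    transitions: pd.DataFrame
    n_excluded_duration: int = 0
    n_dropped_samples: int = 0
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS

    def __post_init__(self) -> None:
        missing = [c for c in TRANSITION_COLS if c not in self.transitions.columns]
        if missing:
            raise ValueError(f"transition table missing columns {missing}")
        t = self.transitions["t_start_ms"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("transitions must be ordered by t_start_ms")
        if (self.transitions["duration_ms"] <= 0).any():
            raise ValueError("transition durations must be positive")
        if (self.transitions["source"] == self.transitions["target"]).any():
            raise ValueError("self-transitions are not allowed")

    def __len__(self) -> int:
        return len(self.transitions)


def _validate_times(df: pd.DataFrame) -> None:
    t = df[TIME_COL].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0])
        raise ValueError(f"non-finite timestamp at row {bad}")
    if len(t) > 1:
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
            kind = "duplicate" if t[bad] == t[bad - 1] else "unsorted"
            raise ValueError(
                f"{kind} timestamp at row {bad}: {t[bad]} follows {t[bad - 1]}"
            )


def read_raw_log(path) -> pd.DataFrame:
    """Read a raw per-frame gaze log CSV (UTF-8, comma-separated, header)."""
    df = pd.read_csv(path)
    if TIME_COL not in df.columns:
        raise ValueError(f"raw log {path} lacks required column {TIME_COL!r}")
    return df


def write_raw_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def clean_samples(
    samples: pd.DataFrame,
    validity_columns: Sequence[str] = PUPIL_COLS,
    placeholder: float = DEFAULT_PLACEHOLDER,
    keep_columns: Optional[Sequence[str]] = None,
) -> tuple:
    """Drop invalid rows and reduce the log to the needed columns.

    A row is invalid when any present validity column equals ``placeholder``
    or is missing.  The output keeps time, gaze target (when present) and
    any ``keep_columns``, in that order.  Returns ``(clean_df, n_dropped)``.

    Raises if timestamps are unsorted or duplicated (the offending row is
    named): transition durations would be meaningless on such a log.
    """
    if TIME_COL not in samples.columns:
        raise ValueError(f"samples lack required column {TIME_COL!r}")
    _validate_times(samples)

    present_validity = [c for c in validity_columns if c in samples.columns]
    if present_validity:
        vals = samples[present_validity]
        invalid = vals.isna().any(axis=1) | (vals == placeholder).any(axis=1)
    else:
        invalid = pd.Series(False, index=samples.index)

    clean = samples.loc[~invalid]
    keep = [TIME_COL]
    if TARGET_COL in samples.columns:
        keep.append(TARGET_COL)
    for c in keep_columns or ():
        if c not in samples.columns:
            raise ValueError(f"requested passthrough column {c!r} not in samples")
        if c not in keep:
            keep.append(c)
    return clean[keep].reset_index(drop=True), int(invalid.sum())


def extract_transitions(
    samples: pd.DataFrame,
    analysis_oois: Iterable[str],
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS,
    participant_id: str = "",
    n_dropped_samples: int = 0,
) -> TransitionTable:
    """Aggregate a cleaned, time-sorted log into a gaze-transition table.

    Only samples whose target is an analysis OOI can start or end a
    transition; samples on other objects (walls, floor, misses) and cleaned
    gaps merely elapse time inside one.  For consecutive OOI samples with
    differing targets, a transition is recorded with ``t_start`` the time of
    the last sample on the source and ``duration`` the gap to the first
    sample on the target.  Transitions longer than ``max_duration_ms`` are
    excluded and counted.
    """
    oois = set(analysis_oois)
    if not oois:
        raise ValueError("analysis OOI set must be non-empty")
    if not (np.isfinite(max_duration_ms) and max_duration_ms > 0):
        raise ValueError(f"max_duration_ms must be positive, got {max_duration_ms}")
    if TARGET_COL not in samples.columns:
        raise ValueError(f"samples lack required column {TARGET_COL!r}")
    _validate_times(samples)

    sub = samples.loc[samples[TARGET_COL].isin(oois), [TIME_COL, TARGET_COL]]
    times = sub[TIME_COL].to_numpy(dtype=float)
    targets = sub[TARGET_COL].to_numpy()

    if len(sub) >= 2:
        change = targets[1:] != targets[:-1]
        t_start = times[:-1][change]
        duration = (times[1:] - times[:-1])[change]
        source = targets[:-1][change]
        target = targets[1:][change]
        ok = duration <= max_duration_ms
        trans = pd.DataFrame(
            {
                "t_start_ms": t_start[ok],
                "duration_ms": duration[ok],
                "source": source[ok],
                "target": target[ok],
            }
        )
        n_excluded = int((~ok).sum())
    else:
        trans = pd.DataFrame(columns=TRANSITION_COLS)
        n_excluded = 0

    return TransitionTable(
        participant_id=participant_id,
        transitions=trans.reset_index(drop=True),
        n_excluded_duration=n_excluded,
        n_dropped_samples=n_dropped_samples,
        max_duration_ms=float(max_duration_ms),
    )


def write_transitions(table: TransitionTable, path) -> None:
    """Write a transition table as CSV: participant,t_start_ms,duration_ms,source,target."""
    out = table.transitions.copy()
    out.insert(0, "participant", table.participant_id)
    out.to_csv(path, index=False)


def read_transitions(path, max_duration_ms: float = DEFAULT_MAX_DURATION_MS) -> TransitionTable:
    df = pd.read_csv(path)
    missing = [c for c in ["participant", *TRANSITION_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"transition CSV {path} missing columns {missing}")
    pids = df["participant"].unique()
    if len(pids) > 1:
        raise ValueError(f"transition CSV {path} mixes participants: {list(pids)}")
    pid = str(pids[0]) if len(pids) else ""
    return TransitionTable(
        participant_id=pid,
        transitions=df[TRANSITION_COLS].reset_index(drop=True),
        max_duration_ms=max_duration_ms,
    )
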