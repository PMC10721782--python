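"""Behavioral readouts: novel-object recognition index and water-maze metrics.

The recognition index RI = T_novel / (T_novel + T_familiar) scores novelty
preference (chance level 0.5). Water-maze metrics operate on a sampled
swim trajectory inside a circular arena: escape latency to a circular
platform region (capped at the trial duration), swum path length, and mean
speed (path length over elapsed time, not displacement).

Platform entry is the first *sample* strictly inside the platform circle —
no interpolation between samples — which matches the discrete output of
video tracking at ≥ 10 Hz. In probe trials the platform is physically
removed; latency is then measured to the former platform location using the
same region.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


class BehaviorError(ValueError):
    pass


@dataclasses.dataclass
class ExplorationRecord:
    """Per-animal exploration times (s) for the novel and familiar object."""

    t_novel_s: float
    t_familiar_s: float

    def __post_init__(self) -> None:
        if self.t_novel_s < 0 or self.t_familiar_s < 0:
            raise BehaviorError("exploration times must be >= 0")


@dataclasses.dataclass
class Trajectory:
    """Timestamped 2D positions (cm) inside a circular arena.

    ``platform_center``/``platform_radius`` define the (possibly former)
    platform region; they are optional for open-field trajectories.
    """

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    arena_center: tuple[float, float] = (0.0, 0.0)
    arena_radius_cm: float = 60.0
    platform_center: tuple[float, float] | None = None
    platform_radius_cm: float | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise BehaviorError("t, x, y must have equal length")
        if len(self.t_s) and np.any(np.diff(self.t_s) <= 0):
            raise BehaviorError("timestamps must be strictly increasing")
        if len(self.t_s):
            r = np.hypot(
                self.x_cm - self.arena_center[0], self.y_cm - self.arena_center[1]
            )
            if np.any(r > self.arena_radius_cm * 1.05):
                raise BehaviorError("trajectory leaves the arena (beyond 5% tolerance)")

    def __len__(self) -> int:
        return len(self.t_s)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **geometry) -> "Trajectory":
        return cls(df["t_s"].values, df["x_cm"].values, df["y_cm"].values, **geometry)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "x_cm": self.x_cm, "y_cm": self.y_cm})


def recognition_index(rec: ExplorationRecord) -> float:
    """RI = T_novel / (T_novel + T_familiar); 0.5 is chance."""
    total = rec.t_novel_s + rec.t_familiar_s
    if total == 0:
        raise BehaviorError("both exploration times are zero: index undefined")
    return rec.t_novel_s / total


@dataclasses.dataclass
class LatencyResult:
    seconds: float
    capped: bool


def escape_latency(traj: Trajectory, trial_cap_s: float = 60.0) -> LatencyResult:
    """Time from trial start to the first sample strictly inside the platform.

    Returns the trial cap (flagged ``capped``) when the animal never reaches
    the platform region within the trial.
    """
    if len(traj) == 0:
        raise BehaviorError("empty trajectory")
    if traj.platform_center is None or traj.platform_radius_cm is None:
        raise BehaviorError("platform geometry undefined")
    d = np.hypot(
        traj.x_cm - traj.platform_center[0], traj.y_cm - traj.platform_center[1]
    )
    inside = np.flatnonzero(d < traj.platform_radius_cm)
    if inside.size == 0:
        return LatencyResult(seconds=float(trial_cap_s), capped=True)
    return LatencyResult(seconds=float(traj.t_s[inside[0]] - traj.t_s[0]), capped=False)


def path_length(traj: Trajectory) -> float:
    """Total swum distance (cm): sum of Euclidean steps between samples."""
    if len(traj) < 2:
        raise BehaviorError("need >= 2 samples for a path")
    return float(np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm)).sum())


def mean_speed(traj: Trajectory) -> float:
    """Mean swim speed (cm/s) = path length / elapsed time."""
    if len(traj) < 2:
        raise BehaviorError("need >= 2 samples for a speed")
    duration = traj.t_s[-1] - traj.t_s[0]
    if duration <= 0:
        raise BehaviorError("zero trial duration")
    return path_length(traj) / float(duration)


def smooth_trajectory(traj: Trajectory, window: int) -> Trajectory:
    """Optional centered moving-average smoothing (off by default upstream)."""
    if window <= 1:
        return traj
    kernel = np.ones(window) / window
    pad = window // 2
    x = np.convolve(np.pad(traj.x_cm, pad, mode="edge"), kernel, mode="same")[
        pad : pad + len(traj)
    ]
    y = np.convolve(np.pad(traj.y_cm, pad, mode="edge"), kernel, mode="same")[
        pad : pad + len(traj)
    ]
    return dataclasses.replace(traj, x_cm=x, y_cm=y)
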