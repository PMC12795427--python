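"""Morris water maze trajectory metrics.

Computes the standard hidden-platform assay parameters from timestamped swim
paths: latency to the platform, distance traversed, floating and thigmotaxis
fractions on training days, and quadrant abidance plus target-zone crossings
on the probe (test) day, when the platform is removed.

Conventions
-----------
* Pool coordinates in meters, origin at the pool center, x toward east and
  y toward north.  Quadrants (NE/NW/SW/SE) are bounded by the axis-aligned
  lines through the pool center with half-open angular membership.
* Each sample carries the duration to the next sample; the last sample
  carries the mean interval.  Irregular frame times are therefore handled.
* Platform contact is a sample point inside the platform disc (no dwell
  requirement), matching protocols that stop the recording on arrival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QUADRANTS",
    "PoolGeometry",
    "Trajectory",
    "TrialMetrics",
    "latency",
    "path_length",
    "floating_fraction",
    "thigmotaxis_fraction",
    "quadrant_abidance",
    "target_zone_crossings",
    "compute_trial_metrics",
    "trial_table",
]

#: Quadrant names in counter-clockwise order starting east-of-north-axis.
QUADRANTS = ("NE", "NW", "SW", "SE")

#: Unit vectors toward each quadrant center (45 degree bisectors).
_QUADRANT_BISECTOR = {
    "NE": (math.sqrt(0.5), math.sqrt(0.5)),
    "NW": (-math.sqrt(0.5), math.sqrt(0.5)),
    "SW": (-math.sqrt(0.5), -math.sqrt(0.5)),
    "SE": (math.sqrt(0.5), -math.sqrt(0.5)),
}


@dataclass
class PoolGeometry:
    """Pool, platform and wall-zone geometry (meters)."""

    pool_center: tuple[float, float] = (0.0, 0.0)
    pool_radius: float = 0.5
    platform_center: tuple[float, float] = (
        -0.25 * math.sqrt(0.5),
        0.25 * math.sqrt(0.5),
    )  # mid-radius of the NW quadrant
    platform_radius: float = 0.04
    wall_zone_width: float = 0.10
    target_radius: float | None = None  # defaults to the platform footprint

    def __post_init__(self) -> None:
        px, py = self.platform_center
        cx, cy = self.pool_center
        if math.hypot(px - cx, py - cy) + self.platform_radius > self.pool_radius:
            raise ValueError("platform disc must lie inside the pool disc")
        if not 0 < self.wall_zone_width < self.pool_radius:
            raise ValueError("wall zone width must be in (0, pool radius)")
        if self.target_radius is None:
            self.target_radius = self.platform_radius

    @classmethod
    def with_platform_in(cls, quadrant: str, **kwargs) -> "PoolGeometry":
        """Geometry with the platform at mid-radius of ``quadrant``."""
        radius = kwargs.get("pool_radius", 0.5)
        ux, uy = _QUADRANT_BISECTOR[quadrant]
        center = kwargs.pop("pool_center", (0.0, 0.0))
        kwargs["platform_center"] = (
            center[0] + 0.5 * radius * ux,
            center[1] + 0.5 * radius * uy,
        )
        return cls(pool_center=center, **kwargs)


@dataclass
class Trajectory:
    """Timestamped swim path."""

    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    rate_hz: float = 14.0
    animal: str | None = None
    day: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if not (len(self.t_s) == len(self.x_m) == len(self.y_m)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) > 1 else 0.0

    def sample_weights(self) -> np.ndarray:
        """Duration carried by each sample (s): interval to the next sample,
        mean interval for the last sample."""
        if len(self) < 2:
            return np.full(len(self), 1.0 / self.rate_hz)
        dt = np.diff(self.t_s)
        return np.append(dt, dt.mean())


@dataclass
class TrialMetrics:
    """All per-trial MWM parameters; probe-day rows leave training metrics
    unset and vice versa."""

    animal: str | None
    day: int | None
    trial: int | None
    latency_s: float | None = None
    distance_m: float | None = None
    floating_pct: float | None = None
    thigmotaxis_pct: float | None = None
    abidance_pct: dict[str, float] | None = None
    crossings: int | None = None


def _dist_to(traj: Trajectory, point: tuple[float, float]) -> np.ndarray:
    return np.hypot(traj.x_m - point[0], traj.y_m - point[1])


def latency(traj: Trajectory, geom: PoolGeometry, cap_s: float = 60.0) -> float:
    """Time of the first sample inside the platform disc, else the cap."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    inside = _dist_to(traj, geom.platform_center) <= geom.platform_radius
    hits = np.flatnonzero(inside)
    if hits.size == 0:
        return cap_s
    return float(traj.t_s[hits[0]] - traj.t_s[0])


def path_length(
    traj: Trajectory,
    until_s: float | None = None,
) -> float:
    """Sum of Euclidean segment lengths, optionally truncated at
    ``until_s`` seconds from trajectory start (training-day convention:
    distance up to platform contact)."""
    if len(traj) < 2:
        warnings.warn("path_length of a trajectory with < 2 samples is 0")
        return 0.0
    x, y, t = traj.x_m, traj.y_m, traj.t_s
    if until_s is not None:
        keep = (t - t[0]) <= until_s + 1e-9
        x, y = x[keep], y[keep]
        if len(x) < 2:
            return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def _speeds(traj: Trajectory) -> np.ndarray:
    """Per-sample speed (m/s) via central differences."""
    if len(traj) < 2:
        return np.zeros(len(traj))
    dxdt = np.gradient(traj.x_m, traj.t_s)
    dydt = np.gradient(traj.y_m, traj.t_s)
    return np.hypot(dxdt, dydt)


def floating_fraction(
    traj: Trajectory,
    speed_thresh_m_s: float = 0.02,
    min_duration_s: float = 1.0,
) -> float:
    """Percent of trial time inside maximal low-speed episodes.

    An episode qualifies when the speed stays below ``speed_thresh_m_s`` for
    at least ``min_duration_s`` contiguously.
    """
    if len(traj) < 2:
        return 0.0
    slow = _speeds(traj) < speed_thresh_m_s
    w = traj.sample_weights()
    total = w.sum()
    floating = 0.0
    # scan maximal runs of slow samples
    i = 0
    n = len(slow)
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            dur = w[i:j].sum()
            if dur >= min_duration_s:
                floating += dur
            i = j
        else:
            i += 1
    return 100.0 * floating / total


def thigmotaxis_fraction(traj: Trajectory, geom: PoolGeometry) -> float:
    """Percent of trial time spent in the wall zone."""
    if len(traj) == 0:
        return 0.0
    r = _dist_to(traj, geom.pool_center)
    in_wall = r > geom.pool_radius - geom.wall_zone_width
    w = traj.sample_weights()
    return 100.0 * float(w[in_wall].sum() / w.sum())


def quadrant_labels(traj: Trajectory, geom: PoolGeometry) -> np.ndarray:
    """Quadrant index of every sample (order :data:`QUADRANTS`), assigned by
    half-open angular convention: NE = [0, pi/2), NW = [pi/2, pi),
    SW = [pi, 3 pi/2), SE = [3 pi/2, 2 pi)."""
    phi = np.arctan2(traj.y_m - geom.pool_center[1], traj.x_m - geom.pool_center[0])
    phi = np.mod(phi, 2 * np.pi)
    return (phi // (np.pi / 2)).astype(int) % 4


def quadrant_abidance(traj: Trajectory, geom: PoolGeometry) -> dict[str, float]:
    """Percent of trial time per pool quadrant; sums to 100."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    labels = quadrant_labels(traj, geom)
    w = traj.sample_weights()
    total = w.sum()
    return {
        name: 100.0 * float(w[labels == k].sum() / total)
        for k, name in enumerate(QUADRANTS)
    }


def target_zone_crossings(traj: Trajectory, geom: PoolGeometry) -> int:
    """Number of entries into the target zone (the former platform disc).

    Outside-to-inside transitions are counted; starting inside counts as one
    entry.
    """
    if len(traj) == 0:
        return 0
    inside = _dist_to(traj, geom.platform_center) <= geom.target_radius
    entries = int(inside[0]) + int(np.sum(inside[1:] & ~inside[:-1]))
    return entries


def compute_trial_metrics(
    traj: Trajectory,
    geom: PoolGeometry,
    cap_s: float = 60.0,
    truncate_distance_at_latency: bool = True,
) -> TrialMetrics:
    """All metrics for one trial.  Training days (1-4) report latency,
    distance, floating and thigmotaxis; the probe day (5) reports quadrant
    abidance and target-zone crossings."""
    m = TrialMetrics(animal=traj.animal, day=traj.day, trial=traj.trial)
    probe = traj.day == 5
    if probe:
        m.abidance_pct = quadrant_abidance(traj, geom)
        m.crossings = target_zone_crossings(traj, geom)
    else:
        m.latency_s = latency(traj, geom, cap_s=cap_s)
        m.distance_m = path_length(
            traj, until_s=m.latency_s if truncate_distance_at_latency else None
        )
        m.floating_pct = floating_fraction(traj)
        m.thigmotaxis_pct = thigmotaxis_fraction(traj, geom)
    return m


def trial_table(
    trajectories: list[Trajectory],
    geom: PoolGeometry,
    schedule: dict[int, list[str]] | None = None,
    cap_s: float = 60.0,
) -> pd.DataFrame:
    """Metrics table with one row per labelled trial.

    ``schedule`` maps day -> list of start quadrants (one per trial); when
    given, each trajectory's (day, trial) must exist in it.
    """
    rows = []
    for traj in trajectories:
        if traj.day is None or traj.trial is None:
            raise ValueError("trajectories must be labelled with day and trial")
        if schedule is not None:
            if traj.day not in schedule or not (
                1 <= traj.trial <= len(schedule[traj.day])
            ):
                raise ValueError(
                    f"(day={traj.day}, trial={traj.trial}) not in the schedule"
                )
        m = compute_trial_metrics(traj, geom, cap_s=cap_s)
        row = {
            "animal": m.animal,
            "day": m.day,
            "trial": m.trial,
            "latency_s": m.latency_s,
            "distance_m": m.distance_m,
            "floating_pct": m.floating_pct,
            "thigmotaxis_pct": m.thigmotaxis_pct,
            "crossings": m.crossings,
        }
        if m.abidance_pct is not None:
            for q in QUADRANTS:
                row[f"abidance_{q}_pct"] = m.abidance_pct[q]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["animal", "day", "trial"]).reset_index(drop=True)
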