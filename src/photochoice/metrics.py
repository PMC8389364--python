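"""The eight Buridan walking metrics.

Given a fixed-rate planar track of a fly shuttling between two opposing
landmark stripes, this module computes:

1.  activity time per minute (s/min) — time not spent in pauses,
    normalized to the experiment duration;
2.  pauses per minute — a pause is any absence of movement lasting
    longer than 1 s (shorter rests count as activity);
3.  distance traveled (mm) — sum of all inter-frame movement lengths;
4.  median speed (mm/s) — per-movement instantaneous speed, with speeds
    above 50 mm/s treated as jumps and excluded from the median;
5.  pause duration (s) — median pause length;
6.  walks per minute — stripe-to-stripe transits, counted by strict
    alternation between the two stripe-approach zones;
7.  stripe deviation (degrees) — per movement, the smaller of the two
    angles between the velocity vector and the vectors from the fly to
    each stripe; the median measures landmark fixation (lower = better);
8.  meander (degrees*s/mm) — per movement, |turning angle| divided by
    instantaneous speed; the median measures track tortuosity.

Frames whose displacement does not exceed ``movement_epsilon`` count as
"no movement"; metrics that need movement (speed, stripe deviation,
meander) are reported as missing (NaN), never 0, when no frame qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, Trajectory, read_trajectory, write_trajectory

__all__ = [
    "MetricsConfig",
    "PauseSegment",
    "MetricsRecord",
    "segment_pauses",
    "activity_time_per_min",
    "pauses_per_min",
    "pause_duration",
    "total_distance",
    "median_speed",
    "walks_per_min",
    "stripe_deviation",
    "meander",
    "compute_all_metrics",
    "write_metrics_table",
    "read_metrics_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "activity_time_per_min",
    "pauses_per_min",
    "distance_traveled",
    "median_speed",
    "pause_duration",
    "walks_per_min",
    "stripe_deviation",
    "meander",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Tunable thresholds of the metric definitions.

    pause_threshold
        Minimum rest span (s) that counts as a pause; rests of exactly
        this length or shorter are activity.
    movement_epsilon
        Per-frame displacement (mm) at or below which a frame counts as
        "no movement"; 0.1 mm per frame is 1 mm/s at 10 Hz, below
        plausible tracking noise.
    jump_threshold
        Speed (mm/s) above which a movement is a jump, excluded from the
        median-speed calculation only (jumps still add to distance).
    zone_half_angle_deg / zone_depth
        A stripe-approach zone is the sector within +/- the half angle of
        a stripe bearing intersected with the outer ``zone_depth`` fraction
        of the platform radius; used only for counting walks.
    """

    pause_threshold: float = 1.0
    movement_epsilon: float = 0.1
    jump_threshold: float = 50.0
    zone_half_angle_deg: float = 30.0
    zone_depth: float = 0.2


@dataclass(frozen=True)
class PauseSegment:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MetricsRecord:
    """The eight metrics for one fly; missing values are NaN."""

    fly_id: str
    activity_time_per_min: float
    pauses_per_min: float
    distance_traveled: float
    median_speed: float
    pause_duration: float
    walks_per_min: float
    stripe_deviation: float
    meander: float
    tube: int | None = None

    def to_dict(self) -> dict:
        d = {"fly_id": self.fly_id}
        if self.tube is not None:
            d["tube"] = self.tube
        d.update({k: getattr(self, k) for k in METRIC_COLUMNS})
        return d


def _moving_mask(traj: Trajectory, eps: float) -> np.ndarray:
    return traj.displacements() > eps


def segment_pauses(traj: Trajectory,
                   pause_threshold: float = 1.0,
                   movement_epsilon: float = 0.1) -> list[PauseSegment]:
    """Maximal rest runs longer than ``pause_threshold`` seconds.

    A rest run is a maximal block of consecutive inter-frame displacements
    not exceeding ``movement_epsilon``; its span runs from the first sample
    of the block to the sample after its last displacement.  Runs whose
    span is <= the threshold are treated as active periods.
    """
    still = ~_moving_mask(traj, movement_epsilon)
    pauses: list[PauseSegment] = []
    i, n = 0, still.size
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            span = traj.t[j] - traj.t[i]
            if span > pause_threshold:
                pauses.append(PauseSegment(float(traj.t[i]), float(traj.t[j])))
            i = j
        else:
            i += 1
    return pauses


def activity_time_per_min(traj: Trajectory,
                          pauses: Iterable[PauseSegment]) -> float:
    """Seconds of activity per minute of experiment, in [0, 60]."""
    total = traj.duration
    paused = sum(p.duration for p in pauses)
    return (total - paused) / total * 60.0


def pauses_per_min(pauses: Iterable[PauseSegment], total_duration: float) -> float:
    return len(list(pauses)) * 60.0 / total_duration


def pause_duration(pauses: Iterable[PauseSegment]) -> float:
    """Median pause length in seconds; NaN when the fly never paused."""
    durations = [p.duration for p in pauses]
    return float(np.median(durations)) if durations else math.nan


def total_distance(traj: Trajectory) -> float:
    """Path length: every movement summed, jumps included."""
    return float(traj.displacements().sum())


def median_speed(traj: Trajectory,
                 jump_threshold: float = 50.0,
                 movement_epsilon: float = 0.1) -> float:
    """Median per-movement speed (mm/s), jumps excluded; NaN if no movement."""
    disp = traj.displacements()
    speeds = disp[disp > movement_epsilon] / traj.dt
    speeds = speeds[speeds <= jump_threshold]
    return float(np.median(speeds)) if speeds.size else math.nan


def _zone_labels(traj: Trajectory, arena: ArenaGeometry,
                 half_angle: float, depth: float) -> np.ndarray:
    """Per-sample zone label: 0 or 1 for a stripe zone, -1 elsewhere."""
    r = np.hypot(traj.x, traj.y)
    theta = np.arctan2(traj.y, traj.x)
    labels = np.full(traj.n_samples, -1, dtype=int)
    in_annulus = r >= (1.0 - depth) * arena.platform_radius
    for k, bearing in enumerate(arena.stripe_bearings):
        dang = np.abs((theta - bearing + math.pi) % (2 * math.pi) - math.pi)
        labels[in_annulus & (dang <= half_angle)] = k
    return labels


def walks_per_min(traj: Trajectory,
                  arena: ArenaGeometry | None = None,
                  config: MetricsConfig = MetricsConfig()) -> float:
    """Stripe-to-stripe transits per minute.

    A walk is counted each time the fly enters the approach zone of one
    stripe when the zone it last entered was the other stripe's; repeated
    returns to the same zone do not count.
    """
    arena = arena or traj.arena
    labels = _zone_labels(traj, arena,
                          math.radians(config.zone_half_angle_deg),
                          config.zone_depth)
    walks = 0
    last = -1
    for lab in labels:
        if lab >= 0 and lab != last:
            if last >= 0:
                walks += 1
            last = lab
    return walks * 60.0 / traj.duration


def _unsigned_angle_deg(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unsigned angle in degrees between rows of v and w, in [0, 180]."""
    dot = np.einsum("ij,ij->i", v, w)
    cross = v[:, 0] * w[:, 1] - v[:, 1] * w[:, 0]
    return np.degrees(np.abs(np.arctan2(cross, dot)))


def stripe_deviation(traj: Trajectory,
                     arena: ArenaGeometry | None = None,
                     movement_epsilon: float = 0.1) -> float:
    """Median deviation (degrees) of the heading from the nearer stripe.

    For every movement the angle between the velocity vector and each of
    the two fly-to-stripe vectors is computed and the smaller is kept
    (the stripe most in front of the animal); NaN if the fly never moved.
    """
    arena = arena or traj.arena
    pos = traj.positions()
    vel = np.diff(pos, axis=0)
    moving = _moving_mask(traj, movement_epsilon)
    if not moving.any():
        return math.nan
    v = vel[moving]
    p = pos[:-1][moving]
    targets = arena.stripe_targets()
    angles = np.minimum(
        _unsigned_angle_deg(v, targets[0] - p),
        _unsigned_angle_deg(v, targets[1] - p),
    )
    return float(np.median(angles))


def meander(traj: Trajectory, movement_epsilon: float = 0.1) -> float:
    """Median |turning angle| / speed over consecutive movements (deg*s/mm).

    The turning angle is taken between two consecutive movement vectors and
    divided by the instantaneous speed of the later movement; pairs broken
    by a no-movement frame are skipped.  NaN if no valid pair exists.
    """
    vel = np.diff(traj.positions(), axis=0)
    moving = _moving_mask(traj, movement_epsilon)
    pair = moving[:-1] & moving[1:]
    if not pair.any():
        return math.nan
    v0 = vel[:-1][pair]
    v1 = vel[1:][pair]
    turn = _unsigned_angle_deg(v0, v1)
    speed = np.hypot(v1[:, 0], v1[:, 1]) / traj.dt
    return float(np.median(turn / speed))


def compute_all_metrics(traj: Trajectory,
                        arena: ArenaGeometry | None = None,
                        config: MetricsConfig = MetricsConfig(),
                        tube: int | None = None) -> MetricsRecord:
    """All eight metrics for one track, with missing-value semantics."""
    arena = arena or traj.arena
    pauses = segment_pauses(traj, config.pause_threshold, config.movement_epsilon)
    return MetricsRecord(
        fly_id=traj.fly_id,
        activity_time_per_min=activity_time_per_min(traj, pauses),
        pauses_per_min=pauses_per_min(pauses, traj.duration),
        distance_traveled=total_distance(traj),
        median_speed=median_speed(traj, config.jump_threshold,
                                  config.movement_epsilon),
        pause_duration=pause_duration(pauses),
        walks_per_min=walks_per_min(traj, arena, config),
        stripe_deviation=stripe_deviation(traj, arena, config.movement_epsilon),
        meander=meander(traj, config.movement_epsilon),
        tube=tube,
    )


def write_metrics_table(records: Iterable[MetricsRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([r.to_dict() for r in records]).to_csv(path, index=False)
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    return df
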