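"""Arena geometry and planar trajectory containers for Buridan-style walking assays.

A fly walks on a circular platform surrounded by a water moat, with two
high-contrast vertical stripes placed on the surrounding cylinder wall,
opposite each other.  Tracks are sampled at a fixed rate (10 Hz by default)
and stored as (t, x, y) with positions in millimetres relative to the
platform centre.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of the walking platform and the two landmark stripes.

    Parameters
    ----------
    platform_radius
        Radius of the walkable platform in mm (default 58.5, i.e. a
        117 mm diameter platform).
    stripe_bearings
        Bearings (radians) of the two stripe centres as seen from the
        platform centre.  Defaults to 0 and pi (opposite each other).
    stripe_distance
        Distance in mm from the platform centre to each stripe.
    stripe_width
        Stripe width in mm (metadata; not used by the metrics).
    """

    platform_radius: float = 58.5
    stripe_bearings: tuple[float, float] = (0.0, math.pi)
    stripe_distance: float = 148.5
    stripe_width: float = 30.0

    def __post_init__(self) -> None:
        if self.platform_radius <= 0:
            raise ValueError("platform_radius must be positive")
        if self.stripe_distance <= self.platform_radius:
            raise ValueError("stripe_distance must exceed platform_radius")
        if len(self.stripe_bearings) != 2:
            raise ValueError("exactly two stripe bearings are required")

    def stripe_targets(self) -> np.ndarray:
        """(2, 2) array of stripe-centre coordinates in the walking plane."""
        b = np.asarray(self.stripe_bearings, dtype=float)
        return self.stripe_distance * np.column_stack([np.cos(b), np.sin(b)])

    def rotated(self, angle: float) -> "ArenaGeometry":
        """Arena rotated rigidly by ``angle`` radians about the centre."""
        b0, b1 = self.stripe_bearings
        return ArenaGeometry(
            platform_radius=self.platform_radius,
            stripe_bearings=(b0 + angle, b1 + angle),
            stripe_distance=self.stripe_distance,
            stripe_width=self.stripe_width,
        )

    def to_dict(self) -> dict:
        return {
            "platform_radius": self.platform_radius,
            "stripe_bearings": list(self.stripe_bearings),
            "stripe_distance": self.stripe_distance,
            "stripe_width": self.stripe_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            platform_radius=float(d["platform_radius"]),
            stripe_bearings=tuple(float(x) for x in d["stripe_bearings"]),
            stripe_distance=float(d["stripe_distance"]),
            stripe_width=float(d.get("stripe_width", 30.0)),
        )


@dataclass
class Trajectory:
    """A fixed-rate planar walking track.

    Timestamps must be strictly increasing with constant spacing; all
    positions must lie on the platform up to ``position_tolerance`` (mm),
    which absorbs tracking noise at the platform edge.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    fly_id: str = ""
    position_tolerance: float = 0.5

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least two samples")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.ptp(dts) > 1e-6:
            raise ValueError("sampling interval must be constant (within 1e-6 s)")
        r = np.hypot(self.x, self.y)
        rmax = self.arena.platform_radius + self.position_tolerance
        if np.any(r > rmax):
            raise ValueError(
                f"trajectory leaves the platform (max radius {r.max():.3f} mm "
                f"> {rmax:.3f} mm)"
            )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions."""
        return np.column_stack([self.x, self.y])

    def displacements(self) -> np.ndarray:
        """(n-1,) Euclidean inter-frame displacement lengths in mm."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def rotated(self, angle: float) -> "Trajectory":
        """Track and arena rotated rigidly by ``angle`` radians."""
        c, s = math.cos(angle), math.sin(angle)
        return Trajectory(
            t=self.t.copy(),
            x=c * self.x - s * self.y,
            y=s * self.x + c * self.y,
            arena=self.arena.rotated(angle),
            fly_id=self.fly_id,
            position_tolerance=self.position_tolerance,
        )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trajectory(traj: Trajectory, csv_path: str | Path,
                     sidecar_path: str | Path | None = None) -> Path:
    """Write a track as CSV (t_s, x_mm, y_mm) plus a JSON geometry sidecar."""
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(csv_path)
    pd.DataFrame({"t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    meta = {
        "arena": traj.arena.to_dict(),
        "sampling_rate": traj.sampling_rate,
        "fly_id": traj.fly_id,
        "position_tolerance": traj.position_tolerance,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trajectory(csv_path: str | Path,
                    sidecar_path: str | Path | None = None) -> Trajectory:
    """Read a track written by :func:`write_trajectory`."""
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("t_s", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"trajectory file {csv_path} lacks column {col!r}")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    arena = ArenaGeometry.from_dict(meta["arena"]) if "arena" in meta else ArenaGeometry()
    return Trajectory(
        t=df["t_s"].to_numpy(),
        x=df["x_mm"].to_numpy(),
        y=df["y_mm"].to_numpy(),
        arena=arena,
        fly_id=str(meta.get("fly_id", csv_path.stem)),
        position_tolerance=float(meta.get("position_tolerance", 0.5)),
    )
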