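"""Choice indices for group phototaxis assays.

Two indices are computed.  For the light/dark T-maze, the elevator-corrected
Choice Index

    CI = (#F_L - c * (#F_D + #F_E)) / #F_T,   c = 1 - 0.036 = 0.964,

where #F_L, #F_D and #F_E are the fly counts in the bright tube, the dark
tube and the (dark) transfer elevator, and the correction compensates for
the extra dark volume the elevator adds.  CI ranges from -0.964 (all flies
dark) to 1 (all flies bright).

For the countercurrent phototaxis paradigm (CPP), the Performance Index

    PI = sum_k k * #F_k / #F_T,   k = 0..5,

the occupancy-weighted mean tube index over the six fractionation tubes.

This module also implements the subgroup pooling rule used before second
(retest) sessions: elevator flies are pooled with the dark tube, and
dark+elevator subgroups from independent replicates are merged until a
minimum group size (40 flies by default) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TMazeSession",
    "CPPTubeCounts",
    "SubgroupPool",
    "DEFAULT_CORRECTION",
    "DEFAULT_ELEVATOR_PROPORTION",
    "correction_factor",
    "compute_ci",
    "compute_pi",
    "pool_subgroups",
    "read_tmaze_sessions",
    "write_tmaze_sessions",
    "read_cpp_counts",
    "write_cpp_counts",
]

#: Volume proportion that the elevator adds to the dark side of the T-maze.
DEFAULT_ELEVATOR_PROPORTION = 0.036
#: Multiplier applied to dark + elevator counts in the Choice Index.
DEFAULT_CORRECTION = 1.0 - DEFAULT_ELEVATOR_PROPORTION


@dataclass(frozen=True)
class TMazeSession:
    """Per-compartment fly counts for one T-maze choice session."""

    n_bright: int
    n_dark: int
    n_elevator: int
    n_total: int
    session_id: str = ""
    replicate: int | None = None
    retest_interval_h: float | None = None

    def __post_init__(self) -> None:
        counts = (self.n_bright, self.n_dark, self.n_elevator, self.n_total)
        if any(c < 0 for c in counts):
            raise ValueError("fly counts must be non-negative")
        if self.n_found > self.n_total:
            raise ValueError(
                "compartment counts exceed the total number of flies"
            )

    @property
    def n_found(self) -> int:
        """Flies recovered in any compartment (total minus lost flies)."""
        return self.n_bright + self.n_dark + self.n_elevator


@dataclass(frozen=True)
class CPPTubeCounts:
    """Tube occupancy counts after one countercurrent session.

    Tube index k (0-based) equals the number of times the flies in that
    tube walked toward the light.
    """

    counts: tuple[int, ...]
    n_total: int
    session_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if any(c < 0 for c in self.counts):
            raise ValueError("tube counts must be non-negative")
        if self.n_total < 0:
            raise ValueError("n_total must be non-negative")
        if sum(self.counts) > self.n_total:
            raise ValueError("tube counts exceed the total number of flies")

    @property
    def n_choices(self) -> int:
        return len(self.counts) - 1

    @property
    def n_found(self) -> int:
        return sum(self.counts)


@dataclass
class SubgroupPool:
    """A (possibly merged) subgroup of flies destined for a second session."""

    source: str  # "bright" | "dark_elevator" | "tube_<k>"
    session_ids: list[str]
    count: int
    meets_minimum: bool


def correction_factor(elevator_proportion: float = DEFAULT_ELEVATOR_PROPORTION) -> float:
    """Multiplier ``1 - elevator_proportion`` applied to dark-side counts.

    ``elevator_proportion`` is the fraction of the dark volume contributed
    by the elevator chamber (0.036 for the apparatus used here), so the
    default return value is 0.964.
    """
    if not 0.0 <= elevator_proportion < 1.0:
        raise ValueError("elevator_proportion must lie in [0, 1)")
    return 1.0 - elevator_proportion


def _denominator(n_found: int, n_total: int,
                 total: Literal["found", "nominal"]) -> int:
    if total == "found":
        return n_found
    if total == "nominal":
        return n_total
    raise ValueError("total must be 'found' or 'nominal'")


def compute_ci(session: TMazeSession,
               correction: float = DEFAULT_CORRECTION,
               total: Literal["found", "nominal"] = "found") -> float:
    """Elevator-corrected Choice Index of one T-maze session.

    With the default correction the index is 1 when every fly chose the
    bright arm and -0.964 when every fly preferred the dark side.  Passing
    ``correction=1.0`` (equivalently ``correction_factor(0)``) yields the
    classic uncorrected preference index.

    Lost flies (total minus recovered) are excluded from the denominator
    by default; ``total='nominal'`` divides by the nominal group size
    instead.
    """
    denom = _denominator(session.n_found, session.n_total, total)
    if denom == 0:
        raise ZeroDivisionError("Choice Index undefined for an empty session")
    return (session.n_bright
            - correction * (session.n_dark + session.n_elevator)) / denom


def compute_pi(tubes: CPPTubeCounts,
               total: Literal["found", "nominal"] = "found") -> float:
    """Performance Index: occupancy-weighted mean tube index (0..n_choices)."""
    denom = _denominator(tubes.n_found, tubes.n_total, total)
    if denom == 0:
        raise ZeroDivisionError("Performance Index undefined for an empty session")
    return sum(k * c for k, c in enumerate(tubes.counts)) / denom


def pool_subgroups(sessions: Sequence[TMazeSession],
                   minimum: int = 40,
                   shuffle_seed: int | None = None) -> list[SubgroupPool]:
    """Form retest subgroups from first-session T-maze replicates.

    Bright flies form one pool per replicate.  Dark and elevator flies are
    combined within each replicate (the elevator is itself dark) and then
    merged across replicates, in input order, until each merged pool holds
    at least ``minimum`` flies; a trailing pool short of the minimum is
    returned flagged with ``meets_minimum=False`` rather than dropped.

    ``shuffle_seed`` randomizes the replicate merge order, mirroring random
    combination of dark+elevator subgroups from different replicates.
    """
    if not sessions:
        raise ValueError("no sessions to pool")
    order = list(range(len(sessions)))
    if shuffle_seed is not None:
        order = list(np.random.default_rng(shuffle_seed).permutation(order))

    pools: list[SubgroupPool] = []
    for s in sessions:
        pools.append(SubgroupPool("bright", [s.session_id], s.n_bright,
                                  s.n_bright >= minimum))
    acc, ids = 0, []
    for i in order:
        s = sessions[i]
        acc += s.n_dark + s.n_elevator
        ids.append(s.session_id)
        if acc >= minimum:
            pools.append(SubgroupPool("dark_elevator", ids, acc, True))
            acc, ids = 0, []
    if ids:
        pools.append(SubgroupPool("dark_elevator", ids, acc, False))
    return pools


# ---------------------------------------------------------------------------
# delimited-text IO

_TMAZE_COLS = ["session_id", "n_bright", "n_dark", "n_elevator", "n_total"]


def write_tmaze_sessions(sessions: Iterable[TMazeSession], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"session_id": s.session_id, "n_bright": s.n_bright, "n_dark": s.n_dark,
         "n_elevator": s.n_elevator, "n_total": s.n_total}
        for s in sessions
    ]
    pd.DataFrame(rows, columns=_TMAZE_COLS).to_csv(path, index=False)
    return path


def read_tmaze_sessions(path: str | Path) -> list[TMazeSession]:
    df = pd.read_csv(path)
    missing = [c for c in _TMAZE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"T-maze table lacks columns {missing}")
    return [
        TMazeSession(int(r.n_bright), int(r.n_dark), int(r.n_elevator),
                     int(r.n_total), session_id=str(r.session_id))
        for r in df.itertuples()
    ]


def write_cpp_counts(sessions: Iterable[CPPTubeCounts], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in sessions:
        row = {"session_id": s.session_id}
        row.update({f"tube_{k}": c for k, c in enumerate(s.counts)})
        row["n_total"] = s.n_total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cpp_counts(path: str | Path) -> list[CPPTubeCounts]:
    df = pd.read_csv(path)
    tube_cols = sorted(
        (c for c in df.columns if c.startswith("tube_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not tube_cols or "n_total" not in df.columns:
        raise ValueError("CPP table needs tube_0..tube_n and n_total columns")
    return [
        CPPTubeCounts(tuple(int(getattr(r, c)) for c in tube_cols),
                      int(r.n_total),
                      session_id=str(getattr(r, "session_id", "")))
        for r in df.itertuples()
    ]
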