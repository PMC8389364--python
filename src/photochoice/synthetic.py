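"""Synthetic fly populations and choice/walking-assay simulators.

The central dichotomy is encoded in two generative population models:

* **spontaneity** — every fly shares one light-choice probability
  ``p_mean`` and successive choices are independent Bernoulli draws, so
  history carries no information ("separate the ones that ran ... the same
  percentage will run");
* **individuality** — each fly owns a latent probability drawn once from
  Beta(alpha, beta) and keeps it for life, so repeated choices reveal
  stable between-fly differences.

Each fly also carries a non-negative ``activity`` trait (truncated-normal
marginal) that may correlate with its light preference through a Gaussian
copula (parameter ``rho``); activity scales walking propensity in the
countercurrent paradigm and locomotor output in the Buridan arena, which is
how the "less phototactic flies are also less active" association is
generated.

All simulators draw from a single explicit :class:`numpy.random.Generator`
seeded by the caller; identical inputs and seed give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .arena import ArenaGeometry, Trajectory
from .fractionation import tube_assignment
from .indices import CPPTubeCounts, TMazeSession, compute_ci, compute_pi

__all__ = [
    "FlyTraits",
    "PopulationModel",
    "TMazeParams",
    "CPPParams",
    "BuridanSimParams",
    "TMazeResult",
    "CPPOutcome",
    "RetestRecord",
    "RetestResult",
    "as_rng",
    "sample_population",
    "simulate_tmaze",
    "simulate_cpp",
    "simulate_retest_protocol",
    "simulate_buridan",
    "write_traits_csv",
    "read_traits_csv",
    "write_cpp_outcome_csv",
    "write_tmaze_outcome_csv",
]

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FlyTraits:
    """Latent per-fly traits driving every simulator.

    p_light is the probability the fly takes the light option on one
    independent choice; activity is a non-negative locomotor scale
    (1 = population reference level).
    """

    fly_id: str
    p_light: float
    activity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_light <= 1.0:
            raise ValueError("p_light must lie in [0, 1]")
        if self.activity < 0.0:
            raise ValueError("activity must be non-negative")


@dataclass(frozen=True)
class PopulationModel:
    """Generative model of a fly cohort.

    kind="spontaneity" gives every fly p_light = p_mean exactly;
    kind="individuality" draws p_light ~ Beta(alpha, beta), whose mean
    alpha/(alpha+beta) must agree with p_mean.  Activity is truncated
    normal (at zero) with the given mean and sd, correlated with p_light
    through a Gaussian copula with latent correlation rho.
    """

    kind: Literal["spontaneity", "individuality"]
    p_mean: float
    alpha: float | None = None
    beta: float | None = None
    activity_mean: float = 1.0
    activity_sd: float = 0.3
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("spontaneity", "individuality"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if not 0.0 <= self.p_mean <= 1.0:
            raise ValueError("p_mean must lie in [0, 1]")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.activity_mean < 0 or self.activity_sd < 0:
            raise ValueError("activity parameters must be non-negative")
        if self.kind == "individuality":
            if self.alpha is None or self.beta is None:
                raise ValueError("individuality model needs alpha and beta")
            if self.alpha <= 0 or self.beta <= 0:
                raise ValueError("beta shapes must be positive")
            mean = self.alpha / (self.alpha + self.beta)
            if abs(mean - self.p_mean) > 1e-9:
                raise ValueError(
                    "p_mean must equal alpha/(alpha+beta) for an "
                    "individuality model"
                )

    @classmethod
    def spontaneity(cls, p_mean: float, **kw) -> "PopulationModel":
        return cls(kind="spontaneity", p_mean=p_mean, **kw)

    @classmethod
    def individuality(cls, alpha: float, beta: float, **kw) -> "PopulationModel":
        return cls(kind="individuality", p_mean=alpha / (alpha + beta),
                   alpha=alpha, beta=beta, **kw)


@dataclass(frozen=True)
class TMazeParams:
    """One T-maze choice session: a Bernoulli light/dark choice per fly,
    preceded by an independent chance of being caught in the elevator."""

    n_flies: int = 80
    elevator_capture_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if not 0.0 <= self.elevator_capture_prob <= 1.0:
            raise ValueError("elevator_capture_prob must lie in [0, 1]")


@dataclass(frozen=True)
class CPPParams:
    """Countercurrent session parameters.

    walk_link specifies how (p_light, activity) combine into the per-choice
    walk probability: "saturating" uses p_light * min(activity/activity_ref, 1)
    (walking costs effort, so sluggish flies walk less even when
    photopositive); "preference" uses p_light alone.
    """

    n_choices: int = 5
    walk_link: Literal["saturating", "preference"] = "saturating"
    activity_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.n_choices < 1:
            raise ValueError("n_choices must be >= 1")
        if self.activity_ref <= 0:
            raise ValueError("activity_ref must be positive")


@dataclass(frozen=True)
class BuridanSimParams:
    """Discrete-time kinematics of a Buridan walking bout."""

    duration: float = 900.0
    sampling_rate: float = 10.0
    base_speed: float = 15.0
    pause_rate: float = 4.0
    pause_duration_mean: float = 3.0
    heading_noise: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if min(self.base_speed, self.pause_rate,
               self.pause_duration_mean, self.heading_noise) < 0:
            raise ValueError("kinematic parameters must be non-negative")


@dataclass
class TMazeResult:
    """Per-fly outcomes plus the aggregated session counts."""

    flies: list[FlyTraits]
    outcomes: list[str]  # each "bright" | "dark" | "elevator"
    session: TMazeSession

    def subgroup(self, *outcomes: str) -> list[FlyTraits]:
        return [f for f, o in zip(self.flies, self.outcomes) if o in outcomes]


@dataclass
class CPPOutcome:
    """Per-fly choice sequences, tube assignments and tube counts."""

    flies: list[FlyTraits]
    sequences: np.ndarray  # (n_flies, n_choices) of 0/1
    tubes: np.ndarray      # (n_flies,) tube index = number of walks
    counts: CPPTubeCounts

    def subgroup(self, tube: int) -> list[FlyTraits]:
        return [f for f, t in zip(self.flies, self.tubes) if t == tube]


def sample_population(model: PopulationModel, n: int, seed=None) -> list[FlyTraits]:
    """Draw ``n`` flies from a population model.

    Gaussian-copula construction: a latent standard-normal pair with
    correlation rho is pushed through the Beta (preference) and
    zero-truncated normal (activity) marginals, so the rank correlation of
    the traits tracks rho while the marginals stay exact.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = as_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = model.rho * z1 + math.sqrt(1.0 - model.rho ** 2) * rng.standard_normal(n)

    if model.kind == "spontaneity":
        p = np.full(n, model.p_mean)
    else:
        p = _st.beta.ppf(_st.norm.cdf(z1), model.alpha, model.beta)

    if model.activity_sd == 0:
        act = np.full(n, model.activity_mean)
    else:
        lo = -model.activity_mean / model.activity_sd
        act = _st.truncnorm.ppf(_st.norm.cdf(z2), lo, np.inf,
                                loc=model.activity_mean, scale=model.activity_sd)
    p = np.clip(p, 0.0, 1.0)
    act = np.maximum(act, 0.0)
    return [FlyTraits(f"fly{i:05d}", float(p[i]), float(act[i])) for i in range(n)]


def simulate_tmaze(flies: Sequence[FlyTraits],
                   params: TMazeParams = TMazeParams(),
                   seed=None,
                   session_id: str = "") -> TMazeResult:
    """One T-maze session: elevator capture, then a light/dark choice.

    Each fly is first caught in the elevator with probability
    ``elevator_capture_prob`` (independent of its preference); conditional
    on exiting, it chooses the bright arm with probability p_light.
    """
    if not flies:
        raise ValueError("no flies to test")
    rng = as_rng(seed)
    n = len(flies)
    p = np.array([f.p_light for f in flies])
    caught = rng.random(n) < params.elevator_capture_prob
    bright = rng.random(n) < p
    outcomes = np.where(caught, "elevator", np.where(bright, "bright", "dark"))
    session = TMazeSession(
        n_bright=int(np.sum(outcomes == "bright")),
        n_dark=int(np.sum(outcomes == "dark")),
        n_elevator=int(np.sum(outcomes == "elevator")),
        n_total=n,
        session_id=session_id,
    )
    return TMazeResult(list(flies), [str(o) for o in outcomes], session)


def walk_probability(fly: FlyTraits, params: CPPParams) -> float:
    """Per-choice probability that a fly walks toward the light."""
    if params.walk_link == "preference":
        return fly.p_light
    return fly.p_light * min(fly.activity / params.activity_ref, 1.0)


def simulate_cpp(flies: Sequence[FlyTraits],
                 params: CPPParams = CPPParams(),
                 seed=None,
                 session_id: str = "") -> CPPOutcome:
    """One countercurrent session of ``n_choices`` walk/stay choices per fly."""
    if not flies:
        raise ValueError("no flies to test")
    rng = as_rng(seed)
    n = len(flies)
    pw = np.array([walk_probability(f, params) for f in flies])
    seqs = (rng.random((n, params.n_choices)) < pw[:, None]).astype(int)
    tubes = np.array([tube_assignment(row) for row in seqs])
    counts = np.bincount(tubes, minlength=params.n_choices + 1)
    return CPPOutcome(
        list(flies), seqs, tubes,
        CPPTubeCounts(tuple(int(c) for c in counts), n, session_id=session_id),
    )


@dataclass(frozen=True)
class RetestRecord:
    """Index of one session within a retest protocol run."""

    label: str          # "original" | "bright" | "dark_elevator" | "tube_<k>"
    session_kind: str   # "first" | "second"
    value: float        # CI (T-maze) or PI (CPP)
    n_flies: int
    meets_minimum: bool
    first_tube: int | None = None


@dataclass
class RetestResult:
    paradigm: str
    records: list[RetestRecord]

    def values(self, label: str, session_kind: str | None = None) -> list[float]:
        return [r.value for r in self.records
                if r.label == label
                and (session_kind is None or r.session_kind == session_kind)]

    def labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.label not in seen:
                seen.append(r.label)
        return seen

    def flagged(self) -> list[RetestRecord]:
        return [r for r in self.records if not r.meets_minimum]


def simulate_retest_protocol(model: PopulationModel,
                             paradigm: Literal["tmaze", "cpp"],
                             replicates: int,
                             seed=None,
                             n_flies: int = 80,
                             minimum: int = 40,
                             tmaze_params: TMazeParams | None = None,
                             cpp_params: CPPParams = CPPParams(),
                             max_first_sessions: int = 500) -> RetestResult:
    """Split-and-retest protocol with subgroup pooling.

    T-maze: each replicate cohort is tested once; the bright subgroup is
    retested per replicate, while dark+elevator flies are pooled across
    replicates until ``minimum`` flies accrue, then retested.  CPP: first
    sessions are run (up to ``max_first_sessions``) accumulating per-tube
    pools of ``minimum`` flies until each tube has ``replicates`` retested
    pools.  Traits persist across sessions, so any history dependence in
    the retests reflects the latent preferences alone.  Pools that never
    reach the minimum are retested anyway and flagged, not dropped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = as_rng(seed)

    if paradigm == "tmaze":
        params = tmaze_params or TMazeParams(n_flies=n_flies)
        records: list[RetestRecord] = []
        pool: list[FlyTraits] = []
        for _ in range(replicates):
            cohort = sample_population(model, params.n_flies, rng)
            first = simulate_tmaze(cohort, params, rng)
            records.append(RetestRecord(
                "original", "first", compute_ci(first.session),
                params.n_flies, True))
            bright = first.subgroup("bright")
            if bright:
                second = simulate_tmaze(bright, params, rng)
                records.append(RetestRecord(
                    "bright", "second", compute_ci(second.session),
                    len(bright), len(bright) >= minimum))
            pool.extend(first.subgroup("dark", "elevator"))
            if len(pool) >= minimum:
                second = simulate_tmaze(pool, params, rng)
                records.append(RetestRecord(
                    "dark_elevator", "second", compute_ci(second.session),
                    len(pool), True))
                pool = []
        if pool:
            second = simulate_tmaze(pool, params, rng)
            records.append(RetestRecord(
                "dark_elevator", "second", compute_ci(second.session),
                len(pool), False))
        return RetestResult("tmaze", records)

    if paradigm != "cpp":
        raise ValueError("paradigm must be 'tmaze' or 'cpp'")

    n_tubes = cpp_params.n_choices + 1
    open_pools: dict[int, list[FlyTraits]] = {k: [] for k in range(n_tubes)}
    closed: dict[int, list[list[FlyTraits]]] = {k: [] for k in range(n_tubes)}
    records = []
    sessions = 0
    while (sessions < max_first_sessions
           and any(len(closed[k]) < replicates for k in range(n_tubes))):
        cohort = sample_population(model, n_flies, rng)
        first = simulate_cpp(cohort, cpp_params, rng)
        records.append(RetestRecord(
            "original", "first", compute_pi(first.counts), n_flies, True))
        sessions += 1
        for fly, tube in zip(first.flies, first.tubes):
            k = int(tube)
            if len(closed[k]) >= replicates:
                continue
            open_pools[k].append(fly)
            if len(open_pools[k]) >= minimum:
                closed[k].append(open_pools[k])
                open_pools[k] = []
    for k in range(n_tubes):
        pools = list(closed[k])
        short = len(pools) < replicates and open_pools[k]
        if short:
            pools.append(open_pools[k])
        for group in pools:
            second = simulate_cpp(group, cpp_params, rng)
            records.append(RetestRecord(
                f"tube_{k}", "second", compute_pi(second.counts),
                len(group), len(group) >= minimum, first_tube=k))
    return RetestResult("cpp", records)


def simulate_buridan(fly: FlyTraits,
                     arena: ArenaGeometry = ArenaGeometry(),
                     params: BuridanSimParams = BuridanSimParams(),
                     seed=None) -> Trajectory:
    """Discrete-time walk between the two stripes with pauses.

    The fly heads for one stripe centre (heading jittered by a normal
    angular perturbation of sd ``heading_noise``) at speed
    ``base_speed * activity``; reaching the platform edge flips the target
    to the opposite stripe.  While walking, a pause starts with per-frame
    hazard ``pause_rate / (60 * sampling_rate)`` and lasts a geometric
    number of frames with mean ``pause_duration_mean * sampling_rate``.
    """
    rng = as_rng(seed)
    dt = 1.0 / params.sampling_rate
    n_steps = int(round(params.duration * params.sampling_rate))
    speed = params.base_speed * fly.activity
    step_len = speed * dt
    radius = arena.platform_radius
    targets = arena.stripe_targets()
    hazard = params.pause_rate / (60.0 * params.sampling_rate)
    mean_pause_frames = max(params.pause_duration_mean * params.sampling_rate, 1.0)

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    x = y = 0.0
    xs[0] = ys[0] = 0.0
    target = 0
    pause_left = 0
    for i in range(1, n_steps + 1):
        if pause_left > 0:
            pause_left -= 1
        elif hazard > 0.0 and rng.random() < hazard:
            pause_left = int(rng.geometric(1.0 / mean_pause_frames))
        else:
            tx, ty = targets[target]
            ang = math.atan2(ty - y, tx - x)
            if params.heading_noise > 0.0:
                ang += params.heading_noise * rng.standard_normal()
            nx = x + step_len * math.cos(ang)
            ny = y + step_len * math.sin(ang)
            r = math.hypot(nx, ny)
            if r >= radius and r > 0.0:
                nx *= radius / r
                ny *= radius / r
                target = 1 - target
            x, y = nx, ny
        xs[i] = x
        ys[i] = y
    t = np.arange(n_steps + 1) * dt
    return Trajectory(t=t, x=xs, y=ys, arena=arena, fly_id=fly.fly_id)


# ---------------------------------------------------------------------------
# delimited-text IO

def write_traits_csv(flies: Iterable[FlyTraits], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"fly_id": f.fly_id, "p_light": f.p_light, "activity": f.activity}
         for f in flies]
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_traits_csv(path: str | Path) -> list[FlyTraits]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [FlyTraits(str(r.fly_id), float(r.p_light), float(r.activity))
            for r in df.itertuples()]


def write_tmaze_outcome_csv(result: TMazeResult, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"fly_id": f.fly_id, "p_light": f.p_light, "activity": f.activity,
          "outcome": o}
         for f, o in zip(result.flies, result.outcomes)]
    ).to_csv(path, index=False)
    return path


def write_cpp_outcome_csv(outcome: CPPOutcome, path: str | Path) -> Path:
    path = Path(path)
    n_choices = outcome.sequences.shape[1]
    rows = []
    for f, seq, tube in zip(outcome.flies, outcome.sequences, outcome.tubes):
        row = {"fly_id": f.fly_id, "p_light": f.p_light, "activity": f.activity}
        row.update({f"choice_{j + 1}": int(c) for j, c in enumerate(seq)})
        row["tube"] = int(tube)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
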