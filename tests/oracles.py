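"""Independent brute-force reference implementations used only by tests.

Everything here is written as naive single-pass scalar loops (or direct
textbook formulas), deliberately avoiding the vectorized code paths of the
package, so that agreement is informative.
"""

from __future__ import annotations

import math

import numpy as np

from photochoice.arena import ArenaGeometry, Trajectory

# ---------------------------------------------------------------------------
# trajectory metrics


def _median(values: list[float]) -> float:
    if not values:
        return math.nan
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def _displacements(traj: Trajectory) -> list[float]:
    out = []
    for i in range(traj.n_samples - 1):
        out.append(math.hypot(traj.x[i + 1] - traj.x[i],
                              traj.y[i + 1] - traj.y[i]))
    return out


def naive_pauses(traj: Trajectory, threshold: float = 1.0,
                 eps: float = 0.1) -> list[tuple[float, float]]:
    disp = _displacements(traj)
    pauses = []
    run_start = None
    for i, d in enumerate(disp + [math.inf]):  # sentinel closes a final run
        if d <= eps and run_start is None:
            run_start = i
        elif d > eps and run_start is not None:
            span = traj.t[i] - traj.t[run_start]
            if span > threshold:
                pauses.append((float(traj.t[run_start]), float(traj.t[i])))
            run_start = None
    return pauses


def naive_activity_time_per_min(traj, pauses) -> float:
    total = traj.t[-1] - traj.t[0]
    paused = sum(e - s for s, e in pauses)
    return (total - paused) / total * 60.0


def naive_pauses_per_min(pauses, total) -> float:
    return len(pauses) * 60.0 / total


def naive_pause_duration(pauses) -> float:
    return _median([e - s for s, e in pauses])


def naive_total_distance(traj) -> float:
    return sum(_displacements(traj))


def naive_median_speed(traj, jump: float = 50.0, eps: float = 0.1) -> float:
    dt = traj.t[1] - traj.t[0]
    speeds = [d / dt for d in _displacements(traj) if d > eps and d / dt <= jump]
    return _median(speeds)


def _zone_of(x: float, y: float, arena: ArenaGeometry,
             half_angle: float, depth: float) -> int:
    r = math.hypot(x, y)
    if r < (1.0 - depth) * arena.platform_radius:
        return -1
    theta = math.atan2(y, x)
    for k, bearing in enumerate(arena.stripe_bearings):
        d = abs((theta - bearing + math.pi) % (2 * math.pi) - math.pi)
        if d <= half_angle:
            return k
    return -1


def naive_walks_per_min(traj, arena=None, half_angle_deg: float = 30.0,
                        depth: float = 0.2) -> float:
    arena = arena or traj.arena
    half = math.radians(half_angle_deg)
    walks, last = 0, -1
    for i in range(traj.n_samples):
        z = _zone_of(traj.x[i], traj.y[i], arena, half, depth)
        if z >= 0 and z != last:
            if last >= 0:
                walks += 1
            last = z
    return walks * 60.0 / (traj.t[-1] - traj.t[0])


def _angle_between(ax, ay, bx, by) -> float:
    """Unsigned angle in degrees, via atan2 of scalar cross and dot."""
    dot = ax * bx + ay * by
    cross = ax * by - ay * bx
    return math.degrees(abs(math.atan2(cross, dot)))


def naive_stripe_deviation(traj, arena=None, eps: float = 0.1) -> float:
    arena = arena or traj.arena
    targets = arena.stripe_targets()
    angles = []
    for i in range(traj.n_samples - 1):
        vx = traj.x[i + 1] - traj.x[i]
        vy = traj.y[i + 1] - traj.y[i]
        if math.hypot(vx, vy) <= eps:
            continue
        a0 = _angle_between(vx, vy, targets[0][0] - traj.x[i],
                            targets[0][1] - traj.y[i])
        a1 = _angle_between(vx, vy, targets[1][0] - traj.x[i],
                            targets[1][1] - traj.y[i])
        angles.append(min(a0, a1))
    return _median(angles)


def naive_meander(traj, eps: float = 0.1) -> float:
    dt = traj.t[1] - traj.t[0]
    vals = []
    for i in range(traj.n_samples - 2):
        v0x = traj.x[i + 1] - traj.x[i]
        v0y = traj.y[i + 1] - traj.y[i]
        v1x = traj.x[i + 2] - traj.x[i + 1]
        v1y = traj.y[i + 2] - traj.y[i + 1]
        if math.hypot(v0x, v0y) <= eps or math.hypot(v1x, v1y) <= eps:
            continue
        turn = _angle_between(v0x, v0y, v1x, v1y)
        speed = math.hypot(v1x, v1y) / dt
        vals.append(turn / speed)
    return _median(vals)


def random_track(seed: int, duration: float = 60.0, rate: float = 10.0,
                 arena: ArenaGeometry | None = None) -> Trajectory:
    """Randomized fixture track with rest runs, ordinary steps and jumps."""
    arena = arena or ArenaGeometry()
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    dt = 1.0 / rate
    x, y = rng.uniform(-20, 20, size=2)
    xs, ys = [x], [y]
    resting = 0
    for _ in range(n):
        if resting > 0:
            resting -= 1
            step = rng.uniform(0, 0.05)  # sub-epsilon tracking jitter
        elif rng.random() < 0.05:
            resting = rng.integers(1, 30)
            step = 0.0
        elif rng.random() < 0.02:
            step = rng.uniform(5.5, 8.0)  # jump (> 50 mm/s at 10 Hz)
        else:
            step = rng.uniform(0.15, 3.0)
        ang = rng.uniform(0, 2 * math.pi)
        nx, ny = x + step * math.cos(ang), y + step * math.sin(ang)
        r = math.hypot(nx, ny)
        if r > arena.platform_radius:
            nx *= arena.platform_radius / r
            ny *= arena.platform_radius / r
        x, y = nx, ny
        xs.append(x)
        ys.append(y)
    t = np.arange(n + 1) * dt
    return Trajectory(t=t, x=np.array(xs), y=np.array(ys), arena=arena,
                      fly_id=f"rand{seed}")


# ---------------------------------------------------------------------------
# rank statistics


def naive_midranks(values: list[float]) -> list[float]:
    """Mid-ranks by direct counting (O(n^2)), independent of rankdata."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def naive_kruskal_h(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H with tie correction, from the textbook formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = naive_midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rbar = sum(ranks[start:start + len(g)]) / len(g)
        h += len(g) * (rbar - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t ** 3 - t for t in ties.values())
    correction = 1.0 - tie_sum / (n ** 3 - n)
    return h / correction


def naive_dunn_z(groups: list[list[float]]) -> dict[tuple[int, int], float]:
    """Dunn's pairwise z from pooled mid-ranks with tie correction."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = naive_midranks(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(sum(ranks[start:start + len(g)]) / len(g))
        sizes.append(len(g))
        start += len(g)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t ** 3 - t for t in ties.values())
    base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            out[(i, j)] = (means[i] - means[j]) / se if se else 0.0
    return out
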