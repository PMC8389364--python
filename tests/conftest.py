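import math

import numpy as np
import pytest

from photochoice.arena import ArenaGeometry, Trajectory


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


def make_track(points, dt=0.1, arena=None, fly_id="fix"):
    """Trajectory from an explicit list of (x, y) points at fixed dt."""
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) * dt
    return Trajectory(t=t, x=pts[:, 0], y=pts[:, 1],
                      arena=arena or ArenaGeometry(), fly_id=fly_id)


def straight_track(speed, duration, dt=0.1, start=(-50.0, 0.0), bearing=0.0,
                   arena=None):
    """Constant-speed straight line (caller keeps it on the platform)."""
    n = int(round(duration / dt))
    step = speed * dt
    pts = [(start[0] + i * step * math.cos(bearing),
            start[1] + i * step * math.sin(bearing)) for i in range(n + 1)]
    big = ArenaGeometry(platform_radius=1e6, stripe_distance=2e6)
    return make_track(pts, dt=dt, arena=arena or big)
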