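import math

import numpy as np
import pytest

from watermaze import PoolConfig, Trajectory


@pytest.fixture
def cfg():
    return PoolConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_traj(pts, dt=0.1, **meta):
    """Trajectory from an (n, 2) point array sampled at ``dt``."""
    pts = np.asarray(pts, dtype=float)
    meta.setdefault("trial_duration", max(90.0, (len(pts) - 1) * dt))
    return Trajectory(t=np.arange(len(pts)) * dt, x=pts[:, 0], y=pts[:, 1], **meta)


class PathMaker:
    """Minimal straight/arc polyline builder for constructing test tracks.

    Independent of the synthetic module: used to build oracle inputs from
    first principles (constant speed, compass headings clockwise from +y).
    """

    def __init__(self, start=(0.0, 0.0), heading=0.0, step=2.0):
        self.pts = [np.asarray(start, dtype=float)]
        self.heading = float(heading)
        self.step = float(step)

    def straight(self, length):
        n = max(1, int(round(length / self.step)))
        for _ in range(n):
            a = math.radians(self.heading)
            self.pts.append(self.pts[-1] + self.step * np.array([math.sin(a), math.cos(a)]))
        return self

    def arc(self, total_deg, radius=6.0):
        per = math.degrees(self.step / radius)
        n = max(1, int(round(abs(total_deg) / per)))
        phi = total_deg / n
        for _ in range(n):
            a = math.radians(self.heading + phi / 2.0)
            self.pts.append(self.pts[-1] + self.step * np.array([math.sin(a), math.cos(a)]))
            self.heading += phi
        return self

    def turn(self, deg):
        self.heading += deg
        return self

    def traj(self, dt=0.1, **meta):
        return make_traj(np.asarray(self.pts), dt=dt, **meta)
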