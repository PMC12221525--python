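import numpy as np
import pytest

from larvathermo import abm
from larvathermo.tracks import Track


@pytest.fixture(scope="session")
def scape():
    """The standard patchy-gradient thermoscape."""
    return abm.ThermoscapeConfig()


@pytest.fixture(scope="session")
def flat_scape():
    """A spatially uniform 21 degC arena (no sources)."""
    return abm.ThermoscapeConfig(sources=())


def straight_track(tid=0, speed_mm_s=1.0, duration_s=30.0, rate=10.0,
                   start=(10.0, 10.0), direction=(1.0, 0.0)):
    """A constant-velocity straight-line track."""
    t = np.arange(int(duration_s * rate)) / rate
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    centroid = np.asarray(start, dtype=float) + speed_mm_s * t[:, None] * d
    head = centroid + 2.0 * d
    return Track(id=tid, t=t, centroid=centroid, head=head,
                 bend_deg=np.zeros(t.size))


@pytest.fixture
def make_straight_track():
    return straight_track
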