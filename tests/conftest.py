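import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from suturemetrics.geometry import Stitch, StitchSet
from suturemetrics.synthetic import ScenarioConfig, default_profiles
from suturemetrics.timing import EventLog, StitchEvents
from suturemetrics.zones import ToolTrace, ZoneConfig


@pytest.fixture
def zones():
    return ZoneConfig(center=(0.0, 0.0), r_cornea=5.75, r_base=15.0)


@pytest.fixture
def profiles():
    return default_profiles()


@pytest.fixture
def scenario():
    return ScenarioConfig()


@pytest.fixture
def ideal_template():
    """Three parallel vertical 2 mm stitches with 1 mm midpoint spacing."""
    stitches = tuple(
        Stitch(index=k, entry=(float(k), -1.0), exit=(float(k), 1.0))
        for k in (1, 2, 3)
    )
    return StitchSet(stitches=stitches, units="mm")


@pytest.fixture
def complete_log():
    """Three completed stitches: durations 120/100/90 s, gaps 60/80 s."""
    return EventLog(
        stitches=(
            StitchEvents(1, 10.0, 130.0),
            StitchEvents(2, 190.0, 290.0),
            StitchEvents(3, 370.0, 460.0),
        ),
        required_stitches=3,
    )


def random_trace(rng, n=200, spread=20.0, p_invisible=0.2):
    t = np.arange(n, dtype=float)
    x = rng.uniform(-spread, spread, n)
    y = rng.uniform(-spread, spread, n)
    visible = rng.random(n) >= p_invisible
    x[~visible] = np.nan
    y[~visible] = np.nan
    return ToolTrace(t=t, x=x, y=y, visible=visible)
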