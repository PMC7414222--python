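import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")

from eventbold.boundaries import KeypressLog
from eventbold.glm import build_design


def make_logs(press_lists, duration=480.0):
    """KeypressLogs from a list of per-observer press-time lists."""
    return [
        KeypressLog(observer_id=f"obs{i:02d}", press_times=np.asarray(p, float), duration=duration)
        for i, p in enumerate(press_lists)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_design(rng):
    """A modest full design: 120 TRs, 3 boundaries, 3 within-event points."""
    n_tr, tr_s = 120, 2.47
    boundaries = np.array([12.0, 110.0, 210.0])
    within = np.array([55.0, 160.0, 260.0])
    edge = 0.2 + 0.1 * np.sin(np.arange(n_tr) / 7.0)
    motion = rng.normal(0, 0.05, (n_tr, 6)).cumsum(axis=0) * 0.1
    design = build_design(boundaries, within, edge, motion, n_tr, tr_s)
    return design, boundaries, within
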