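import numpy as np
import pytest

import phonosim as ps


@pytest.fixture(scope="session")
def frame():
    return ps.LarynxFrame()


@pytest.fixture(scope="session")
def a0max(frame):
    return ps.baseline_max_area(frame)


@pytest.fixture(scope="session")
def base_gaw(a0max):
    return ps.baseline_gaw(148.0, a0max, 2000)


@pytest.fixture(scope="session")
def gc1_motion_pair(frame, base_gaw):
    """(symmetric, asymmetric) motion fields for GC1 with defaults."""
    gc = ps.make_gc("GC1", frame=frame)
    gaw = ps.modify_gaw(base_gaw, gc)
    sym = ps.build_motion(gaw, frame, gc, (1.0, 1.0), 200)
    asym = ps.build_motion(gaw, frame, gc, (0.5, 1.0), 200)
    return sym, asym


@pytest.fixture(scope="session")
def study():
    """The full ten-case study at default resolution (runs once per session)."""
    return ps.run_study()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
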