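import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from geodereg.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def small_phantom():
    """64x64, 10-frame phantom for fast unit-level checks."""
    return generate(PhantomSpec(seed=11, shape=(64, 64), n_frames=10, n_pre=3))


@pytest.fixture(scope="session")
def default_phantom():
    """The full default acquisition layout (128x128, 22 frames, 6 pre)."""
    return generate(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(default_phantom):
    """Full-pipeline result on the default phantom (computed once)."""
    from geodereg.pipeline import run

    return run(default_phantom.observed_series)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
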