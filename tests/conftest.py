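import numpy as np
import pytest

from meaperf import ArtifactSpec, UnitSpec, gen_recording
from meaperf.config import PipelineConfig


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def short_recording():
    """10 s, 8 channels, two strong units (trough 8x noise), no artifacts."""
    specs = [UnitSpec(channel=1, rate_hz=4.0, vpp_uV=80.0),
             UnitSpec(channel=5, rate_hz=3.0, vpp_uV=80.0)]
    return gen_recording(10.0, 8, 25000.0, specs, 6.0, seed=11)


@pytest.fixture(scope="session")
def artifact_recording():
    """20 s, 16 channels, units plus both artifact classes."""
    specs = [UnitSpec(channel=2, rate_hz=4.0, vpp_uV=80.0),
             UnitSpec(channel=10, rate_hz=4.0, vpp_uV=80.0)]
    art = ArtifactSpec(n_amplitude=6, n_coincident=6)
    return gen_recording(20.0, 16, 25000.0, specs, 6.0, art, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
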