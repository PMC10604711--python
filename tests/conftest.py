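import numpy as np
import pytest

from facesym import FrameSequence, default_pair_table
from facesym.synthetic import make_template


@pytest.fixture(scope="session")
def pairs():
    return default_pair_table()


@pytest.fixture(scope="session")
def template():
    return make_template(seed=0)


@pytest.fixture()
def symmetric_seq(template):
    """Single-frame sequence of a perfectly symmetric frontal face."""
    return FrameSequence(frames=(template.to_frame(),), subject_id="sym")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
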