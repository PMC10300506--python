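import numpy as np
import pytest

from solepress.foot_model import build_standard_outline
from solepress.synthetic import SyntheticTaskConfig, gen_standing, gen_walking


@pytest.fixture(scope="session")
def outline():
    return build_standard_outline()


@pytest.fixture(scope="session")
def standing_pair():
    """Two-foot quiet standing, 10 s, default sway and noise."""
    cfg = SyntheticTaskConfig(task_kind="standing", duration_s=10.0, seed=11)
    return gen_standing(cfg)


@pytest.fixture(scope="session")
def walking_recording():
    """10-stride walking recording with ground truth."""
    cfg = SyntheticTaskConfig(task_kind="walking", duration_s=12.0, seed=7)
    return gen_walking(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
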