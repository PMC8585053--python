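import numpy as np
import pytest
from hypothesis import settings

from graftdens import DEFAULT_LABEL_TABLE, LabelMap, PhantomSpec, generate_phantom

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default-geometry phantom with zero noise: recovery must be exact."""
    return generate_phantom(PhantomSpec(noise_sd_hu=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(seed=7))


def make_labelmap(shape, spacing=0.4):
    """All-air label map to paint regions onto, for handcrafted geometry."""
    data = np.full(shape, DEFAULT_LABEL_TABLE["air"], dtype=np.int32)
    return LabelMap(data, (spacing,) * 3, label_table=dict(DEFAULT_LABEL_TABLE))


@pytest.fixture
def blank_labels():
    return make_labelmap((48, 48, 32))
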