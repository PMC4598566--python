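import numpy as np
import pytest

from ciliadyn import synthdata


@pytest.fixture
def small_field():
    """A small synthetic two-channel field with ground truth (fast)."""
    params = synthdata.FieldParams(field_size_px=(384, 384), n_centrosomes=15,
                                   ciliation_fraction=0.6, n_z=5)
    stack, truth = synthdata.generate_cilia_field(params, seed=7)
    return params, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
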