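import numpy as np
import pytest

from polypseg.specs import ArchitectureSpec, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A miniature two-depth network for fast training/determinism tests."""
    return ArchitectureSpec(
        variant_name="tiny",
        encoder_channels=[4, 8],
        convs_per_depth=[(1, 0), (1, 0)],
        input_size=(8, 8),
    )


@pytest.fixture
def synth_spec():
    return SyntheticSpec(resolution=(32, 32), seed=7)
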