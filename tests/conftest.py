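import pytest

from curvislice.phantom import (
    make_phantom,
    make_tape_phantom,
    make_two_layer_phantom,
)


@pytest.fixture(scope="session")
def two_layer():
    spec = make_two_layer_phantom(seed=0)
    vol, truth = make_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def tape():
    spec = make_tape_phantom(seed=2)
    vol, truth = make_phantom(spec)
    return spec, vol, truth
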