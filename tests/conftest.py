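import numpy as np
import pytest

from hadet.data import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 16-image dataset (2 train / 2 val per class) at 96 px."""
    out = tmp_path_factory.mktemp("tinyds")
    return generate_dataset(
        out, seed=5, image_size=96,
        counts={"train": (2, 2, 2, 2), "val": (2, 2, 2, 2)},
    )
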