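import numpy as np
import pytest

from prcrecon.kernels import build_kernel_bank
from prcrecon.volume import ImageVolume


@pytest.fixture(scope="session")
def small_bank():
    """5^3 kernel bank at modest statistics for operator tests."""
    return build_kernel_bank(kernel_size=(5, 5, 5), n_events=20_000, seed=1)


@pytest.fixture(scope="session")
def tiny_bank():
    """3^3 kernel bank for dense-matrix oracles."""
    return build_kernel_bank(kernel_size=(3, 3, 3), n_events=20_000, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_label_map():
    gen = np.random.default_rng(7)
    return ImageVolume(
        gen.integers(0, 3, (16, 16, 8)).astype(np.int8), 2.0, content_kind="label"
    )
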