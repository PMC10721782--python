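import numpy as np
import pytest

from lymphomorph import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_region_labels():
    """One near-volume-filling region, the workhorse fixture for recovery."""
    return sd.gen_label_volume(
        (32, 64, 64), [(1, "CTX", {"box": ((1, 31), (1, 63), (1, 63))})]
    )


@pytest.fixture
def two_region_labels():
    return sd.gen_label_volume(
        (24, 48, 48),
        [
            (1, "PFC", {"box": ((2, 22), (2, 22), (2, 46))}),
            (2, "HIP", {"box": ((2, 22), (26, 46), (2, 46))}),
        ],
    )
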