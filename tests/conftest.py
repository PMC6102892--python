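import numpy as np
import pytest

from strexpand.annotation import STRLocus


@pytest.fixture
def toy_loci() -> list[STRLocus]:
    return [
        STRLocus("chr1", 1000, 1030, "AGC", 10.0),
        STRLocus("chr1", 2000, 2060, "AGC", 20.0),
        STRLocus("chr1", 5000, 5040, "AT", 20.0),
        STRLocus("chr2", 1000, 1048, "AAG", 16.0),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
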