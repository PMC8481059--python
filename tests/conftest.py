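import numpy as np
import pytest

from eiwss import TwoSampleData, load_dataset


@pytest.fixture(scope="session")
def jute() -> TwoSampleData:
    ds = load_dataset("jute")
    return TwoSampleData(ds.x, ds.y)


@pytest.fixture(scope="session")
def carbon() -> TwoSampleData:
    ds = load_dataset("carbon")
    return TwoSampleData(ds.x, ds.y)


@pytest.fixture(scope="session")
def toy44() -> TwoSampleData:
    """Fixed 4+4-point sample, small enough for exhaustive grid oracles."""
    return TwoSampleData(np.array([0.6, 1.1, 1.7, 2.9]),
                         np.array([0.5, 1.0, 1.9, 3.5]))
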