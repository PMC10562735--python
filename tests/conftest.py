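import numpy as np
import pytest

from mrscreen.harmonize import HarmonizedSet


@pytest.fixture
def toy_harmonized() -> HarmonizedSet:
    """Five strong instruments with Wald ratios 1..5 and unit outcome SEs."""
    k = 5
    return HarmonizedSet(
        np.array([f"s{i}" for i in range(k)], dtype=object),
        np.ones(k),
        np.full(k, 0.1),
        np.arange(1.0, k + 1.0),
        np.ones(k),
    )
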