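import numpy as np
import pytest

from hybridzone import ZoneConfig, simulate_zone


@pytest.fixture(scope="session")
def default_zone():
    """One default synthetic zone shared by read-only tests."""
    return simulate_zone(ZoneConfig(seed=42))


@pytest.fixture(scope="session")
def wide_zone():
    """A zone whose flanks extend far enough to contain pure parental sites."""
    return simulate_zone(
        ZoneConfig(seed=7, site_positions=np.linspace(-600, 1200, 13))
    )
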