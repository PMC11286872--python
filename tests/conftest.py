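import numpy as np
import pytest

from cortisim import (SheetSpec, TemporalParams, calibrate_theta_thresh,
                      generate_maps, sheet_center_for_ecc)


@pytest.fixture(scope="session")
def params():
    return TemporalParams()


@pytest.fixture(scope="session")
def theta_thresh(params):
    return calibrate_theta_thresh(params)


@pytest.fixture(scope="session")
def sheet_ecc3():
    """Small cortical patch centered on the 3 deg representation."""
    return generate_maps(SheetSpec(center=sheet_center_for_ecc(3.0),
                                   extent=(4.0, 4.0), spacing=0.05, seed=0))


@pytest.fixture(scope="session")
def big_sheet():
    """24x24 mm patch for map statistics."""
    return generate_maps(SheetSpec(extent=(24.0, 24.0), spacing=0.1, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
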