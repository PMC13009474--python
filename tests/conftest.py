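import pytest
from hypothesis import settings

from aslmsim import calibration as cal
from aslmsim.config import default_config

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def twin():
    """The reference instrument twin (full 3200-row chip)."""
    return default_config()


@pytest.fixture(scope="session")
def small_twin():
    """A 320-row twin with proportionally scaled static map, for fast tests."""
    return default_config(
        optics={"n_rows": 320, "n_cols": 320},
        shutter={"n_rows": 320},
        voice_coil={
            "static_map_coeffs": [32.5, 33.0, 0.0, 3.5],
            "position_range_um": [-5.0, 70.0],
        },
    )


@pytest.fixture(scope="session")
def noise_free_curve(twin):
    """Static calibration of the reference twin without photon noise."""
    return cal.build_static_calibration(twin, seed=1, noise=False)
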