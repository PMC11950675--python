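import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import macpolar as mp

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def mfi_8x7():
    """Deterministic 8-line x 7-marker MFI matrix from the generator."""
    return mp.simulate_panel_study(mp.SyntheticConfig(seed=7))


@pytest.fixture
def small_events():
    df = pd.DataFrame({
        "FSC": [50_000.0, 100_000.0, 150_000.0, 5_000.0],
        "SSC": [30_000.0, 60_000.0, 90_000.0, 1_000.0],
        "CD86": [10.0, 20.0, 30.0, 40.0],
    })
    return mp.EventTable("S1", df)


#: The eight printed score pairs and their published classifications.
TABLE2_ROWS = [
    ("COLO320", -0.46, 0.48, "Mixed", "moderate"),
    ("DLD1", 1.31, -0.06, "M1", "strong"),
    ("LoVo", 0.89, -1.16, "M1", "moderate"),
    ("LS1034", -0.23, 0.47, "Mixed", "moderate"),
    ("NCI-H508", -0.17, -0.39, "Unpolarized", "none"),
    ("HT-29", -0.34, -0.45, "Unpolarized", "none"),
    ("HCT116", -0.63, 1.61, "M2", "strong"),
    ("SW620", 0.58, -0.51, "M1", "moderate"),
]
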