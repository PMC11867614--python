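import numpy as np
import pytest

import looptrack as lt
from looptrack.engine import SettingsSpec
from looptrack.synth import constant_speed_truth

TRACK_MM = 2000.0
N_BINS = 50


@pytest.fixture(scope="session")
def suite_small():
    """Compact benchmark fixture set shared by analysis tests."""
    return lt.make_benchmark_suite(seed=7, n_laps=20, n_cells=40)


@pytest.fixture(scope="session")
def uniform_truth():
    return constant_speed_truth(track_length_mm=TRACK_MM, n_laps=20)


@pytest.fixture()
def reward_settings():
    return SettingsSpec.from_dict({
        "track": {"length_mm": TRACK_MM, "scale_mm_per_tick": 0.5},
        "step_ms": 10,
        "contexts": [
            {"id": "rz", "type": "reward", "mode": "operant",
             "zones": [{"center_mm": 1000, "radius_mm": 100}],
             "valve_ms": 50},
        ],
    })
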