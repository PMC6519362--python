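import numpy as np
import pytest

from msiscope.panel_io import MarkerDefinition
from msiscope.synthetic_data import SimulationConfig, synthetic_panel


@pytest.fixture(scope="session")
def panel24():
    return synthetic_panel(24, seed=1)


@pytest.fixture(scope="session")
def panel4():
    return synthetic_panel(4, seed=7)


@pytest.fixture()
def marker_a8():
    """A single A8 marker with hand-written flanks."""
    return MarkerDefinition(
        marker_id="M01",
        chrom="chr1",
        start=1000,
        end=1008,
        repeat_unit="A",
        wt_length=8,
        left_flank="GTCGTACGTC",
        right_flank="CTGACGGTAC",
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
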