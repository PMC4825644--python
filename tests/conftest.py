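import numpy as np
import pytest

from radmap.panel_io import GenotypePanel
from radmap.simulate import SimConfig, simulate_cross


def make_panel(dosages, marker_ids=None, individual_ids=None) -> GenotypePanel:
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypePanel(
        marker_ids=marker_ids or [f"m{i + 1}" for i in range(d.shape[0])],
        individual_ids=individual_ids or [f"ind{j + 1}" for j in range(d.shape[1])],
        dosages=d,
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free default-size cross (24 chromosomes x 50 markers, 49 F2)."""
    return simulate_cross(SimConfig(seed=11, error_rate=0.0, missing_rate=0.0))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default cross with 1% miscalls and 2% missing calls."""
    return simulate_cross(SimConfig(seed=7))


@pytest.fixture(scope="session")
def dense_clean_sim():
    """Error-free cross at 100 markers/chromosome (>20 bins per chromosome)."""
    return simulate_cross(
        SimConfig(seed=5, error_rate=0.0, missing_rate=0.0, markers_per_chromosome=100)
    )
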