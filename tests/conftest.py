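import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from ecostoichnet import (
    OTUTable,
    PipelineConfig,
    SimulationConfig,
    generate_bundle,
)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Scaled-down study bundle: same design, fewer taxa for fast networks."""
    return SimulationConfig(
        n_taxa={"fungi": 60, "bacteria": 90},
        n_cliques=4,
        clique_size=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return generate_bundle(small_sim_config)


@pytest.fixture()
def tiny_otu() -> OTUTable:
    counts = pd.DataFrame(
        np.array(
            [
                [10, 20, 30, 12, 18, 25, 9, 14, 22],
                [5, 0, 8, 3, 7, 2, 6, 1, 4],
                [100, 90, 80, 95, 85, 88, 92, 97, 83],
                [0, 0, 1, 0, 0, 0, 2, 0, 0],
            ]
        ),
        index=["taxA", "taxB", "taxC", "taxD"],
        columns=[f"s{i}" for i in range(1, 10)],
    )
    return OTUTable(counts, "fungi")
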