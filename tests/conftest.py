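import numpy as np
import pytest

from phylodemo.scenarios import DemeTrajectory, Scenario
from phylodemo.coalescent import SampleConfig
from phylodemo.seqevo import Alignment
from phylodemo.diversity import PopulationMap


@pytest.fixture(scope="session")
def single_deme_scenario():
    """One panmictic deme of constant size 1,000 (analytic coalescent case)."""
    traj = DemeTrajectory(deme_id=1, N0=1000, N1=1000, t_span=1400)
    return Scenario(name="PLAH", demes=(traj,), source_deme=1,
                    migration_prob=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_alignment():
    """Two populations x three sequences with known pairwise distances."""
    seqs = [
        "AAAAAAAAAA",
        "AAAAAAAAAT",
        "AAAAAAAATT",
        "GGAAAAAAAA",
        "GGAAAAAAAT",
        "GGCAAAAAAA",
    ]
    labels = [f"s{i}" for i in range(6)]
    return Alignment.from_strings(labels, seqs)


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        assignments={f"s{i}": ("P1" if i < 3 else "P2") for i in range(6)}
    )


@pytest.fixture
def two_lineage_config():
    return SampleConfig(sizes={1: 2})
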