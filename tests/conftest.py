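import numpy as np
import pandas as pd
import pytest

from nursepart.core_data import AbundanceTable, SampleMetadata, SoilChemistry, AFLPMatrix
from nursepart.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study design covering all six habitats."""
    return SimulationConfig(
        seed=20260919,
        n_granite_exscapa=3,
        n_limestone_exscapa=3,
        n_limestone_longiscapa=3,
        samples_per_site_per_location=4,
        n_motus=150,
        n_loci=120,
        read_depth=4000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def toy_counts() -> AbundanceTable:
    df = pd.DataFrame(
        [[10, 10, 20], [5, 0, 5], [0, 0, 8]],
        index=["a", "b", "c"],
        columns=["m1", "m2", "m3"],
        dtype=float,
    )
    return AbundanceTable(df, mode="counts")


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    rows = []
    for site, bedrock, cluster in [
        ("s1", "granite", "exscapa"),
        ("s2", "limestone", "longiscapa"),
    ]:
        for loc, tag in [("cushion", "c"), ("bare", "b")]:
            for k in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{site}{tag}{k}",
                        "site": site,
                        "bedrock": bedrock,
                        "location": loc,
                        "cluster": cluster,
                        "elevation": 2500.0,
                        "x": 100.0 * (1 if site == "s1" else 50),
                        "y": 10.0 * k,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
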