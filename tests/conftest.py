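import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from parasnail import (
    SampleDesign,
    SimulationConfig,
    generate_design,
    generate_sample_design,
    generate_truth,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def mixed_config() -> SimulationConfig:
    """Small mixed-class dataset shared by downstream-stage tests."""
    return SimulationConfig(
        n_genes=300,
        probes_per_gene=5,
        n_empty_spots=60,
        frac_parallel_directional=0.10,
        frac_parallel_nondirectional=0.05,
        frac_locality_specific=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def mixed_dataset(mixed_config):
    return simulate_dataset(mixed_config)


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, probes_per_gene=5, n_empty_spots=60, seed=7)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return simulate_dataset(null_config)


def make_sample_design(n_per_group: int, assay: str = "expression",
                       localities=("Burela", "Roncudo", "Silleiro")) -> SampleDesign:
    rows = []
    for loc in localities:
        for eco in ("crab", "wave"):
            for rep in range(1, n_per_group + 1):
                rows.append((f"{assay[:4]}_{loc[:3]}_{eco}_{rep:02d}", assay, eco, loc, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "assay", "ecotype", "locality", "replicate"])
    )
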