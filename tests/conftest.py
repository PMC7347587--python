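import numpy as np
import pandas as pd
import pytest

from uvkin import (
    GenomeSpec,
    SurvivalDataset,
    default_constants,
    default_ecoli_genome,
)


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def genome():
    return default_ecoli_genome()


def make_noiseless_dataset(k, n0, times=tuple(range(30, 301, 30)), replicates=3,
                           plated_volume_ml=3.0, strain="model"):
    """Exact model observations in the CFU-record schema (no sampling)."""
    rows = []
    for rep in range(1, replicates + 1):
        rows.append({"time_s": 0.0, "replicate": rep, "dilution_factor": 1.0,
                     "cfu_per_ml": n0 / plated_volume_ml})
        for t in times:
            n1 = max(n0 - k * np.log(t), 0.0)
            rows.append({"time_s": float(t), "replicate": rep,
                         "dilution_factor": 1.0,
                         "cfu_per_ml": n1 / plated_volume_ml})
    return SurvivalDataset(strain=strain, records=pd.DataFrame(rows),
                           plated_volume_ml=plated_volume_ml)


@pytest.fixture
def noiseless_dataset():
    return make_noiseless_dataset(k=5e7, n0=3e8)


def random_genome(rng: np.random.Generator) -> GenomeSpec:
    """A physically plausible random genome for property tests."""
    return GenomeSpec(
        base_pairs_nj=rng.uniform(1e6, 1e7),
        genome_volume_vg=rng.uniform(1e-13, 1e-12),
        genome_thickness_dx=rng.uniform(1e-5, 1e-4),
        impact_section_sigma=rng.uniform(1e-16, 1e-15),
        label="random",
    )
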