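import numpy as np
import pandas as pd
import pytest

from lofsplice.io import CountMatrix, SampleSheet
from lofsplice.simulate import SimulationConfig, combine_datasets, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=120, n_events=80, samples_per_group=3, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Per-dataset counts + ground truth, generated once per session."""
    per_dataset, truth = simulate_counts(small_config)
    counts, sheet = combine_datasets(per_dataset)
    return counts, sheet, truth


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples with a matching sheet."""
    counts = CountMatrix(
        pd.DataFrame(
            [[10, 20, 12, 18], [100, 210, 90, 200], [5, 9, 4, 11]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "dataset": ["fratta"] * 4,
                "genotype": ["WT", "WT", "HOM", "HOM"],
                "arm": ["KO"] * 4,
            }
        )
    )
    return counts, sheet


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
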