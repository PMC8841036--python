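import numpy as np
import pandas as pd
import pytest

from microdepth import (CountTable, SampleMetadata, SimulationParams,
                        simulate_dataset)


@pytest.fixture
def toy_table() -> CountTable:
    counts = np.array([[10, 5, 0, 1],
                       [0, 8, 2, 0],
                       [4, 4, 4, 4]])
    return CountTable(["s1", "s2", "s3"], ["a1", "a2", "a3", "a4"], counts)


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {"plot": [1, 1, 2], "layer": ["S", "M", "D"], "time": ["T1"] * 3},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
    return SampleMetadata(df)


def balanced_metadata(n_plots=2, n_times=2) -> SampleMetadata:
    rows = []
    for p in range(1, n_plots + 1):
        for t in range(1, n_times + 1):
            for layer in ("S", "M", "D"):
                rows.append((f"P{p}T{t}{layer}", p, layer, f"T{t}"))
    df = pd.DataFrame(rows, columns=["sample_id", "plot", "layer", "time"]
                      ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def sim_default():
    """One small-but-complete simulated dataset shared across tests."""
    params = SimulationParams(n_asvs=500, library_size=10_000, seed=11)
    return simulate_dataset(params)
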