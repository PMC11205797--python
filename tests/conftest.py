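"""Shared fixtures: tiny hand-built datasets and mid-size synthetic ones."""

import numpy as np
import pandas as pd
import pytest

import patchassembly as pa


@pytest.fixture
def tiny_table() -> pa.AbundanceTable:
    """3 taxa x 4 samples with easily hand-checked counts."""
    df = pd.DataFrame(
        [[5, 0, 2, 1],
         [3, 4, 0, 1],
         [2, 6, 8, 8]],
        index=["ASV_A", "ASV_B", "ASV_C"],
        columns=["S1", "S2", "S3", "S4"])
    return pa.AbundanceTable(df)


@pytest.fixture
def tiny_tree() -> pa.Phylogeny:
    return pa.Phylogeny.from_newick_string(
        "((ASV_A:0.1,ASV_B:0.2):0.3,ASV_C:0.5);")


@pytest.fixture
def tiny_metadata() -> pa.SampleMetadata:
    df = pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "patch_id": ["P1", "P1", "P2", "P2"],
        "area_m2": [4.0, 4.0, 592.0, 592.0],
        "TN": [3.3, 3.1, 2.6, 2.5],
        "pH": [5.8, 5.7, 5.8, 5.9],
    }).set_index("sample_id")
    return pa.SampleMetadata(df)


@pytest.fixture
def tiny_triple(tiny_table, tiny_tree, tiny_metadata):
    return tiny_table, tiny_tree, tiny_metadata


@pytest.fixture(scope="session")
def neutral_small() -> pa.SyntheticDataset:
    """20-sample / 100-taxon neutral dataset used by several null-model tests."""
    layout = pa.PatchLayout(areas=(4.0, 592.0), quadrats=(10, 10))
    params = pa.SimulationParams(n_taxa=100, reads_per_sample=1000, m=0.1,
                                 regime="neutral", seed=5)
    return pa.simulate_neutral_dataset(params, layout)


@pytest.fixture(scope="session")
def neutral_small_metrics(neutral_small) -> pd.DataFrame:
    return pa.assembly_metrics(neutral_small.table, neutral_small.phylogeny,
                               n_null=99, seed=7)


def patch_labels(metrics) -> tuple[np.ndarray, np.ndarray]:
    """Patch ids of the two samples of each pair (P*_Q* naming)."""
    a = np.asarray(metrics.index.get_level_values("sample_a").str.split("_").str[0])
    b = np.asarray(metrics.index.get_level_values("sample_b").str.split("_").str[0])
    return a, b
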