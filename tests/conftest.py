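"""Shared fixtures.

The end-to-end pipeline fixture (simulated genome -> features -> matched
negatives -> 80/20 split -> RF) is expensive (the fold energies dominate),
so it is built once per session and shared by the synthetic-data,
evaluation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from srnarank import classifiers
from srnarank.dataset_builder import SamplingConfig
from srnarank.pipeline import FixtureDatasets, build_fixture_datasets, train_and_score
from srnarank.synthetic_data import SimulationConfig


FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_pipeline() -> FixtureDatasets:
    return build_fixture_datasets(
        SimulationConfig(seed=FIXTURE_SEED),
        SamplingConfig(seed=FIXTURE_SEED),
        split_seed=FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def fixture_rf(fixture_pipeline):
    """(trained RF model, test AUPRC) on the session fixture."""
    return train_and_score(fixture_pipeline, "RF", seed=FIXTURE_SEED)


def separable_table(n: int = 100, seed: int = 0, informative=("distLeftORF", "distRightORF")):
    """A feature table where only the given columns separate the classes."""
    import pandas as pd

    from srnarank.context_features import FEATURE_COLUMNS
    from srnarank.dataset_builder import LabeledDataset

    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.concatenate([np.ones(half, dtype=int), np.zeros(n - half, dtype=int)])
    data = {}
    for col in FEATURE_COLUMNS:
        if col in informative:
            shift = np.where(labels == 1, 8.0, -8.0)
            data[col] = shift + rng.normal(0, 1, n)
        elif col.startswith("sameStrand"):
            data[col] = rng.integers(0, 2, n)
        else:
            data[col] = rng.normal(0, 1, n)
    df = pd.DataFrame(data)
    df.insert(0, "name", [f"row{i}" for i in range(n)])
    return LabeledDataset(df, labels)
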