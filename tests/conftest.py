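import numpy as np
import pandas as pd
import pytest

from relapsesig.cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def tiny_matrix():
    """2 genes x 3 samples with easy hand-checkable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]],
        index=pd.Index(["g1", "g2"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def eight_sample_matrix():
    """8-sample, 3-gene fixture with two labelled classes for CV oracles."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(1, 9)]
    matrix = pd.DataFrame(
        rng.normal(size=(3, 8)),
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=samples,
    )
    matrix.loc["gA"] += np.array([1, 1, 1, 1, -1, -1, -1, -1]) * 1.5
    labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=samples, name="relapse")
    return matrix, labels
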