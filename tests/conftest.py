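import numpy as np
import pandas as pd
import pytest

from deconsensus import (
    CONTROL,
    TREATMENT,
    CountMatrix,
    SampleDesign,
    SimParams,
    simulate_dataset,
)


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.integers(0, 500, size=(50, 4)),
        index=[f"G{i}" for i in range(50)],
        columns=["c1", "c2", "t1", "t2"],
    )
    return CountMatrix(df)


@pytest.fixture
def small_design(small_counts) -> SampleDesign:
    return SampleDesign(
        group=pd.Series(
            [CONTROL, CONTROL, TREATMENT, TREATMENT],
            index=small_counts.sample_ids,
        )
    )


@pytest.fixture(scope="session")
def sim_strong():
    """A simulated dataset with a strong effect (logfc 4) for trend checks."""
    params = SimParams(n_genes=3000, reps_per_group=4, pdeg=0.1, logfc=4.0, seed=101)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def sim_medium():
    params = SimParams(n_genes=2000, reps_per_group=3, pdeg=0.05, logfc=2.0, seed=7)
    return simulate_dataset(params)
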