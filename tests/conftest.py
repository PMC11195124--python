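import numpy as np
import pandas as pd
import pytest

from visig import PipelineConfig, SimDesign, generate_bulk_cohort


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_counts():
    """A reproducible 50-gene x 6-sample NB count fixture."""
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(5, 0.02, size=(50, 6)).astype(int)
    return pd.DataFrame(counts,
                        index=[f"g{i:02d}" for i in range(50)],
                        columns=[f"s{j}" for j in range(6)])


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default synthetic discovery-style cohort (103 samples, planted modules)."""
    design = SimDesign(n_samples=103)
    counts, samples, truth = generate_bulk_cohort(design, seed=11)
    return design, counts, samples, truth
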