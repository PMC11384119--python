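import numpy as np
import pytest

from purplemap.pipeline import AnalysisParams, analyze_dataset, simulate_dataset
from purplemap.simdata import ChromosomeSpec, CrossConfig


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic dataset shared across tests."""
    return simulate_dataset(seed=1000)


@pytest.fixture(scope="session")
def default_analysis(default_bundle):
    return analyze_dataset(default_bundle, AnalysisParams())


@pytest.fixture()
def small_config():
    """A light cross layout for fast tests."""
    return CrossConfig(
        n_offspring=40,
        chromosomes=(
            ChromosomeSpec("chr1", 50.0, 20),
            ChromosomeSpec("chr2", 50.0, 20),
        ),
        causal_chrom="chr2",
        causal_cm=25.0,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
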