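import pandas as pd
import pytest

from dmrscape import synthetic
from dmrscape.config import AnalysisConfig
from dmrscape.dmr_catalog import build_catalog, filter_calls


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def cohort_manifest():
    """17 tumors, 10 matched normals, 2 confirmed never-smokers and 4
    confirmed smokers — the cohort structure the analysis was designed for."""
    return synthetic.default_manifest()


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset (reference, methylomes, calls) shared by
    read-only tests."""
    return synthetic.generate_dataset(seed=3)


@pytest.fixture(scope="session")
def catalog(dataset):
    filtered = filter_calls(dataset.calls, bin_grid=dataset.bin_grid)
    return build_catalog(filtered, dataset.comparisons)


def intervals(*triples) -> pd.DataFrame:
    """Shorthand interval frame builder for tests."""
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])
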