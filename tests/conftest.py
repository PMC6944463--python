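import numpy as np
import pytest

from occuclass import SyntheticConfig, run_pipeline


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The package's reference study conditions (2 Mb genome, 300 genes,
    150 bound promoters, 2+2 replicates), fixed seed."""
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full pipeline run shared by every end-to-end check."""
    return run_pipeline(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A down-scaled configuration for fast structural/determinism checks."""
    return SyntheticConfig(
        genome_length=200_000,
        n_genes=40,
        n_bound_promoters=20,
        n_direct_down=8,
        n_indirect=6,
        n_silent=4,
        depth_ip=150_000,
        depth_input=150_000,
        seed=5,
    )
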