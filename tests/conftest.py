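import pytest
from hypothesis import settings

import pirnakit as pk

settings.register_profile("pirnakit", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("pirnakit")


def small_ref_sizes():
    return {
        "piRNA_cluster": [1200] * 4,
        "coding_RNA": [800] * 2,
        "noncoding_RNA": [500] * 2,
        "repeat": [400] * 2,
        "intron": [600] * 2,
        "element": 2000,
    }


@pytest.fixture(scope="session")
def small_config():
    return pk.SimConfig(
        seed=7,
        n_mirna=300,
        n_mili=600,
        n_miwi=600,
        error_rate=0.0,
        pingpong_fraction=0.2,
        element_fraction=0.3,
        ref_sizes=small_ref_sizes(),
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return pk.build_reference_catalog(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_catalog):
    """Error-free simulated library: (reads, truth)."""
    return pk.simulate_library(small_config, small_catalog)


@pytest.fixture(scope="session")
def preprocessed(small_library, small_config):
    reads, _ = small_library
    params = pk.PreprocessParams(adapter=small_config.adapter)
    return pk.preprocess_library(reads, params)


@pytest.fixture(scope="session")
def index(small_catalog):
    return pk.build_index(small_catalog)
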