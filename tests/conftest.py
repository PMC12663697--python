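import numpy as np
import pytest

from panfam import build_pan_family, load_manifest, scaled_default_config, simulate_pan_family


@pytest.fixture(scope="session")
def scaled_dataset(tmp_path_factory):
    """Desk-scale synthetic dataset: 12 accessions, 30 OGGs, seed 1."""
    out = tmp_path_factory.mktemp("scaled")
    dataset = simulate_pan_family(scaled_default_config(seed=1), out)
    return dataset, out


@pytest.fixture(scope="session")
def scaled_manifest(scaled_dataset):
    _, out = scaled_dataset
    return load_manifest(out)


@pytest.fixture(scope="session")
def scaled_oggs(scaled_manifest):
    """One shared iterative build (the expensive fixture of the suite)."""
    return build_pan_family(scaled_manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
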