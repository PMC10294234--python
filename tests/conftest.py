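import pytest

from tkiclone.simulate import SimulationConfig, simulate_all, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """Synthetic dataset at the modelled study conditions (60x coverage)."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def deep_dataset():
    """Same design at very high coverage, where sampling noise is negligible."""
    return simulate_all(SimulationConfig(seed=13, depth_mean=10_000))


@pytest.fixture(scope="session")
def written_dataset(dataset, tmp_path_factory):
    """The 60x dataset written to disk, plus its manifest."""
    outdir = tmp_path_factory.mktemp("synthetic")
    manifest = write_dataset(dataset, outdir)
    return dataset, outdir, manifest
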