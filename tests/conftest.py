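import pytest

from adjacoex.simulate import default_config, simulate_bundle, write_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default planted world, seed 1: (annotation, bands, truth, cna, expr,
    mirna, regulator sets)."""
    return simulate_bundle(default_config(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The same world written to disk as a file bundle."""
    out = tmp_path_factory.mktemp("fixture")
    write_fixture_bundle(default_config(seed=1), out)
    return out
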