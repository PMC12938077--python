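import pytest

from coaxstack import GeneratorConfig, generate_dataset, load_turner_params


@pytest.fixture(scope="session")
def params():
    return load_turner_params()


@pytest.fixture(scope="session")
def small_dataset():
    """A few hundred planted-rule pairs for fast classifier tests."""
    return generate_dataset(GeneratorConfig(seed=11, n_junctions=300))


@pytest.fixture(scope="session")
def study_dataset():
    """Full study conditions: >= 2000 pairs at the 6:1 target imbalance."""
    ds = generate_dataset(GeneratorConfig(seed=101, n_junctions=1750))
    assert len(ds.table) >= 2000
    return ds
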