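import pytest

from methmark import simulate


@pytest.fixture(scope="session")
def bundle():
    """One seeded synthetic study (validation-cohort sizes, 100 genes),
    shared across tests that only read it."""
    return simulate.gen_bundle(simulate.TruthConfig(seed=1), n_genes=100)


@pytest.fixture(scope="session")
def markers(bundle):
    return sorted(bundle.config.marker_freqs)
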