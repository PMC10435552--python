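import pytest

from pollenrisk import load_builtin_fixtures, run_reproduction
from pollenrisk.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def bundle():
    """The packaged transcription of the study's printed tables."""
    return load_builtin_fixtures()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One deterministic synthetic study at the default conditions."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def reproduction_report():
    return run_reproduction(n_perm=199, seed=7)
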