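import pytest

from eluent.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """300 seeded synthetic reactions shared across read-only tests."""
    return generate(SyntheticConfig(n_reactions=300, seed=42))
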