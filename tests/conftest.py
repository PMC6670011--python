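import pytest

from ampcall.simulate import synthetic_catalogue, synthetic_panel


@pytest.fixture(scope="session")
def small_panel():
    """Anchored 6-amplicon synthetic panel plus the reference it lives in."""
    panel, reference = synthetic_panel(n_amplicons=6, seed=7)
    return panel, reference


@pytest.fixture(scope="session")
def small_catalogue(small_panel):
    panel, _ = small_panel
    catalogue, candidates = synthetic_catalogue(panel, n_per_amplicon=2, seed=8)
    return catalogue, candidates
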