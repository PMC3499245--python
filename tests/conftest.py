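import pytest

from hgtscan.simulate import SimParams, generate_hit_table


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_transcripts=300, seed=11)


@pytest.fixture(scope="session")
def small_study(small_params):
    """One small simulated study shared across read-only tests."""
    hits, truth = generate_hit_table(small_params)
    return hits, truth, small_params
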