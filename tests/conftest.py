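import pytest

from pgxcea import load_parameters


@pytest.fixture(scope="session")
def base_ps():
    """The packaged base-case parameter set (shared read-only)."""
    return load_parameters()


@pytest.fixture()
def ps(base_ps):
    """A private mutable copy of the base case."""
    return base_ps.copy()
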