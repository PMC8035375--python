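import pytest
from hypothesis import settings

from borealref import build_revised_matrix, build_plan

# property tests must be reproducible run to run
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def revised_matrix():
    """Default revised reference matrix (25/25/50 ages, equal thirds)."""
    return build_revised_matrix()


@pytest.fixture(scope="session")
def default_plan(revised_matrix):
    return build_plan(revised_matrix)
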