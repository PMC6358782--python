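import pytest
from hypothesis import settings

from artmet.biotransform import enumerate_candidates

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from artmet.compare import load_reference_table


@pytest.fixture(scope="session")
def records():
    """The packaged 39-row metabolite summary table."""
    return load_reference_table()


@pytest.fixture(scope="session")
def candidates():
    """Default candidate set enumerated from artemisinin."""
    return enumerate_candidates("C15H22O5")


@pytest.fixture(scope="session")
def candidates_by_label(candidates):
    return {c.label: c for c in candidates}
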