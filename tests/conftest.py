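import pytest

from impact_tool import fixtures


@pytest.fixture(scope="session")
def study_catalog():
    """The full 123-indicator panel catalog."""
    return fixtures.study_catalog()


@pytest.fixture(scope="session")
def tool_catalog():
    """The 71-active-indicator tool catalog (after merges/exclusions)."""
    return fixtures.development_catalog()
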