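import pytest

from omnictrl import DesignSpec, assemble


@pytest.fixture(scope="session")
def default_spec() -> DesignSpec:
    return DesignSpec(seed=42)


@pytest.fixture(scope="session")
def design(default_spec):
    """The default design, built once per session."""
    return assemble(default_spec)
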