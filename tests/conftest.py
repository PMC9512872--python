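import pytest

from growlite.config import GrowConfig
from growlite.fixtures import FixtureSpec, plant_case


@pytest.fixture
def cfg():
    return GrowConfig()


@pytest.fixture
def planted():
    """Factory for seeded planted cross-growing cases."""

    def _make(seed=0, **kwargs):
        return plant_case(FixtureSpec(seed=seed, **kwargs))

    return _make
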