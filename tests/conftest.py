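import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_code39

from barcodeassay import AssayLayout, RenderScenario


@pytest.fixture(scope="session")
def layout() -> AssayLayout:
    """Default physical geometry (3/0.5/2 mm strips, 600 dpi)."""
    return AssayLayout()


@pytest.fixture(scope="session")
def clean_scenario() -> RenderScenario:
    """No blur, no lighting, no noise — ideal optics."""
    return RenderScenario(blur_sigma=0.0)


def positive_scenario(odr: float = 1.0, **kw) -> RenderScenario:
    return RenderScenario(strip_odrs={1: odr, 2: odr, 3: odr, 4: odr}, **kw)


def negative_scenario(odr: float = 1.0, **kw) -> RenderScenario:
    return RenderScenario(strip_odrs={1: 0.0, 2: odr, 3: 0.0, 4: odr}, **kw)
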