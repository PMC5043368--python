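import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from beetox.datasets import honey_bee_endpoint, tested_endpoints


@pytest.fixture
def table_endpoints():
    """The six tested endpoint entries of the study's summary table."""
    return tested_endpoints()


@pytest.fixture
def all_endpoints():
    """Tested entries plus the literature honey-bee surrogate endpoint."""
    return tested_endpoints() + [honey_bee_endpoint()]
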