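import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from mirsitemut.formats_io import MatureMiRNA
from mirsitemut.synthetic_data import make_study_fixtures


@pytest.fixture(scope="session")
def mirna_x() -> MatureMiRNA:
    """Worked-example miRNA: seed ACAGUAU, 8mer site AUACUGUA."""
    return MatureMiRNA(name="hsa-miR-X", sequence="UACAGUAUAGAUGAUGUACU")


@pytest.fixture(scope="session")
def study_fixtures():
    return make_study_fixtures(seed=11)
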