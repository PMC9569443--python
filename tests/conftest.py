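import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference_values importable

from laminprm.panels import PANEL_NAMES, build_panel

# A 30-residue toy prelamin A used by unit tests so they run without the
# bundled fixtures: tryptic structure, CAAX terminus, and a deletion
# interval containing the 15-residue cleavage site (after residue 12).
TOY_PRELAMIN = "AGELKSSQTRSVAGKLNDTRSQSSQNCSIM"
TOY_DELETION = (11, 20)


@pytest.fixture(scope="session")
def panels():
    return {name: build_panel(name) for name in PANEL_NAMES}


@pytest.fixture()
def toy_prelamin():
    return TOY_PRELAMIN
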