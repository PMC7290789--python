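import numpy as np
import pytest

from imkbnct import (
    CellLineParams,
    DomainGeometry,
    RadiationQuality,
    load_cell_line,
)


@pytest.fixture(scope="session")
def geom() -> DomainGeometry:
    return DomainGeometry()


@pytest.fixture(scope="session")
def co60() -> RadiationQuality:
    """Acute photon reference quality (y* = y_D = 2.26 keV/μm)."""
    return RadiationQuality.from_y_star(2.26)


@pytest.fixture(scope="session")
def hx34() -> CellLineParams:
    return load_cell_line("hx34")


@pytest.fixture(scope="session")
def m8() -> CellLineParams:
    return load_cell_line("m8")


@pytest.fixture(scope="session")
def melj() -> CellLineParams:
    return load_cell_line("mel-j")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
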