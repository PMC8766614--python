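import numpy as np
import pytest

from memdiv.constriction import MembraneParams

A_CELL = float(np.pi * 1.0 * 3.0)   # pi*D*L, D = 1 um, L = 3 um


@pytest.fixture
def params():
    """Reference calibration: kappa0 = 12 kBT, kappa_crit(u0) = 36 kBT."""
    return MembraneParams()


@pytest.fixture
def cell_area():
    return A_CELL
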