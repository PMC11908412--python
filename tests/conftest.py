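import numpy as np
import pytest

from quenchcal.geometry import Atom, DyeParameters, StructureModel
from quenchcal import synthetic as syn


@pytest.fixture(scope="session")
def ruler_distances():
    """Mean dye separations of the 0P/3P/5P/6P rulers (AV engine, default
    dye parameters); session-scoped because the AV grids are the slowest
    fixtures in the suite."""
    return {n: syn.ruler_distance(n) for n in (0, 3, 5, 6)}


@pytest.fixture()
def lone_attachment():
    """A structure containing only the attachment atom: the accessible
    volume around it is a free-space ball."""
    atom = Atom("SG", 1, "CYS", "S", 1.8, np.zeros(3))
    return StructureModel(atoms=[atom], n_pro=0,
                          attachment_atoms=(atom.id(), atom.id()))


@pytest.fixture()
def coarse_dye():
    """Short-linker dye parameters for cheap AV computations in unit tests."""
    return DyeParameters(linker_length=6.0, linker_width=3.0,
                         dye_radius=2.0, grid_spacing=1.0)
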