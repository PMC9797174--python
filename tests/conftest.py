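import numpy as np
import pytest

from rtspc.dose_model import Contour, DoseGrid, Structure, StructureSet


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture
def constant_grid():
    """10x10x10 grid, 2 mm spacing, centers at 1,3,...,19 mm, 2 Gy everywhere."""
    return DoseGrid(
        origin=(1.0, 1.0, 1.0),
        spacing=(2.0, 2.0, 2.0),
        values=np.full((10, 10, 10), 2.0),
        frame_id="F1",
    )


def square_contour(z, x0=0.0, x1=20.0, y0=0.0, y1=20.0):
    return Contour(z=z, points=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))


@pytest.fixture
def square_structure():
    """Square 20 mm contour on the z=1 plane (first slice of constant_grid)."""
    return Structure(name="PTV1", contours=(square_contour(1.0),))


@pytest.fixture
def square_structure_set(square_structure):
    return StructureSet(structures=(square_structure,), frame_id="F1")
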