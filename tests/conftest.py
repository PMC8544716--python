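import numpy as np
import pytest

from smcoloc.locdata import CellROI


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def box_roi():
    return CellROI(cell_id=7, shape="box", lo=(-10, -10, -10), hi=(10, 10, 10))


@pytest.fixture
def rod_roi():
    """A typical rod-shaped cell: 2 µm long, 0.8 µm wide spherocylinder."""
    return CellROI(
        cell_id=0, shape="spherocylinder", center=(0, 0, 0),
        axis=(1, 0, 0), length=2000.0, radius=400.0,
    )
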