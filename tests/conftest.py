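import numpy as np
import pytest

from vsdassay.field import CultureGeometry, Electrode
from vsdassay.membrane import PassiveMembrane


@pytest.fixture
def mem():
    """Passive properties of a 2-week differentiated cultured cell."""
    return PassiveMembrane(capacitance=18.3, input_resistance=3.3, resting_potential=-29.7)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def square_bipole_geom(unit_square):
    return CultureGeometry(
        domain=unit_square,
        electrodes=[Electrode((0.25, 0.5), 0.03, +1), Electrode((0.75, 0.5), 0.03, -1)],
    )


def structured_strip_mesh(nx=20, ny=10):
    """Structured unit-square mesh with the x=0 / x=1 edges tagged as electrodes
    at polarity -1 / +1 (exact 1D analytic solution: phi = x - 1/2)."""
    from vsdassay.field import TriMesh

    xs, ys = np.linspace(0, 1, nx + 1), np.linspace(0, 1, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(ny):
        for i in range(nx):
            a = j * (nx + 1) + i
            b, c, d = a + 1, a + nx + 1, a + nx + 2
            tris.append([a, b, d])
            tris.append([a, d, c])
    tags = ["electrode_0" if x < 1e-12 else "electrode_1" if x > 1 - 1e-12 else "interior"
            for x, y in nodes]
    return TriMesh(nodes, np.array(tris), tags,
                   {"electrode_0": -1, "electrode_1": +1})
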