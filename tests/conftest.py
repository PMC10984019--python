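import numpy as np
import pytest

from lungmech import fem, geometry, synthetic


@pytest.fixture(scope="session")
def circle_stack():
    """Identical circular outlines (cylinder) over 5 slices."""
    ang = 2 * np.pi * np.arange(48) / 48
    circ = lambda r: np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return synthetic.AxialOutlineStack(
        outlines=[circ(0.05)] * 5,
        inner_outlines=[circ(0.045)] * 5,
        z=np.arange(5) * 0.01)


@pytest.fixture(scope="session")
def lung_outlines():
    return synthetic.generate_lung_outlines(seed=5)


@pytest.fixture(scope="session")
def lung_mesh_small(lung_outlines):
    outer, inner = geometry.loft_outlines(lung_outlines)
    return geometry.mesh_solids(outer, inner, target_element_count=350)


@pytest.fixture(scope="session")
def ball_mesh():
    return geometry.ball_tet_mesh(0.05, n=5)


@pytest.fixture(scope="session")
def sphere_options():
    """Solver options for the free sphere: pressure on the whole surface,
    rigid modes pinned."""
    return fem.SolverOptions(pressure_labels=("surface",), spring_labels=(),
                             inplane_labels=(), pin_rigid_body=True)
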