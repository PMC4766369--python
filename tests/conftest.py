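import numpy as np
import pytest

from edgewall import fem, geometry
from edgewall.geometry import CellRowSpec


@pytest.fixture(scope="session")
def unit_cell_spec():
    """One 10x10 μm cell with 1 μm walls (wall area 36 μm²)."""
    return CellRowSpec(
        n_cells=1, cell_width=10.0, cell_height=10.0,
        outer_wall_thickness=1.0, anticlinal_wall_thickness=1.0,
        inner_wall_thickness=1.0,
    )


@pytest.fixture(scope="session")
def default_spec():
    return CellRowSpec()


@pytest.fixture(scope="session")
def unit_cell_mesh(unit_cell_spec):
    return geometry.mesh_domain(geometry.build_cell_row(unit_cell_spec), 0.5)


@pytest.fixture(scope="session")
def wall_material():
    return fem.WallMaterial(elastic_modulus=5e8, poisson_ratio=0.45)


def solve_quarter_ring(n_radial, a=4.0, b=6.0, pressure=5e5,
                       material=None):
    """Quarter-annulus pressurized-ring solve with symmetry constraints."""
    material = material or fem.WallMaterial(5e8, 0.45)
    mesh = fem.quarter_annulus_mesh(a, b, n_radial, 3 * n_radial)
    tol = 1e-9
    fix_y = np.flatnonzero(np.abs(mesh.nodes[:, 1]) < tol)
    fix_x = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < tol)
    load = fem.LoadCase(
        turgor_pressure=pressure,
        pressure_edges=mesh.boundary_edges["inner"],
        fixed_x_nodes=fix_x,
        fixed_y_nodes=fix_y,
    )
    sol = fem.solve(mesh, {"ring": material}, load)
    return mesh, sol


def ring_displacement_error(n_radial, a=4.0, b=6.0, pressure=5e5,
                            material=None):
    """Max relative radial-displacement error against the closed form."""
    material = material or fem.WallMaterial(5e8, 0.45)
    mesh, sol = solve_quarter_ring(n_radial, a, b, pressure, material)
    r = np.linalg.norm(mesh.nodes, axis=1)
    ur = np.einsum("ij,ij->i", sol.displacements, mesh.nodes / r[:, None])
    exact = fem.lame_radial_displacement(r, a, b, pressure, material)
    return float(np.abs(ur - exact).max() / np.abs(exact).max())
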