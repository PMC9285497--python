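"""Quasi-static electric solve against the annulus closed form and its
structural properties (symmetry, maximum principle, scaling laws)."""

import numpy as np
import pytest
import scipy.sparse as sp

from ooablate.electric import ElectricSystem, scenario_electric_system
from ooablate.meshing import structured_rectangle_mesh
from ooablate.oracles import annulus_conductance, annulus_potential

A, B, L, V0, SIGMA = 0.001, 0.01, 0.01, 30.0, 0.3


def annulus_system(nr, nz):
    mesh = structured_rectangle_mesh(A, B, 0.0, L, nr, nz)
    inner = np.unique(mesh.boundary_edges["rmin"])
    outer = np.unique(mesh.boundary_edges["rmax"])
    return mesh, ElectricSystem(mesh, inner, outer)


@pytest.fixture(scope="module")
def solved():
    mesh, sys_ = annulus_system(96, 12)
    sigma = np.full(mesh.n_triangles, SIGMA)
    return mesh, sys_, sys_.solve(sigma, V0)


def test_annulus_potential_matches_closed_form(solved):
    mesh, _, field = solved
    exact = annulus_potential(mesh.nodes[:, 0], A, B, V0)
    assert np.abs(field.V - exact).max() < 0.005 * V0


def test_delivered_power_matches_annulus_conductance(solved):
    _, sys_, field = solved
    exact = annulus_conductance(SIGMA, L, A, B) * V0**2
    assert field.power == pytest.approx(exact, rel=0.01)
    assert sys_.delivered_power(field) == pytest.approx(field.power, rel=1e-12)


def test_error_quarters_under_mesh_halving():
    errs = []
    for nr in (32, 64, 128):
        mesh, sys_ = annulus_system(nr, 4)
        field = sys_.solve(np.full(mesh.n_triangles, SIGMA), V0)
        exact = annulus_potential(mesh.nodes[:, 0], A, B, V0)
        errs.append(np.abs(field.V - exact).max())
    assert errs[0] / errs[1] > 2.8
    assert errs[1] / errs[2] > 2.8


def test_stiffness_symmetry_and_homogeneity():
    mesh, sys_ = annulus_system(12, 4)
    sigma = np.full(mesh.n_triangles, SIGMA)
    K = sys_.elem.csr(sys_.assemble(sigma))
    assert abs(K - K.T).max() == 0.0
    # scaling sigma scales the matrix, not the solution
    K2 = sys_.elem.csr(sys_.assemble(3.0 * sigma))
    assert abs(K2 - 3.0 * K).max() < 1e-9 * abs(K).max()
    v1 = sys_.solve(sigma, V0).V
    v2 = sys_.solve(3.0 * sigma, V0).V
    assert np.allclose(v1, v2, atol=1e-9 * V0)


def test_linearity_and_joule_quadratic_scaling():
    mesh, sys_ = annulus_system(12, 4)
    sigma = np.full(mesh.n_triangles, SIGMA)
    f1 = sys_.solve(sigma, V0)
    f2 = sys_.solve(sigma, 2 * V0)
    assert np.allclose(f2.V, 2 * f1.V, rtol=1e-10)
    assert np.allclose(f2.q_rf, 4 * f1.q_rf, rtol=1e-9)
    # q_rf = sigma |E|^2 by construction
    assert np.allclose(f1.q_rf, sigma * f1.E_mag**2, rtol=1e-12)


def test_zero_voltage_gives_identically_zero_field():
    mesh, sys_ = annulus_system(8, 4)
    field = sys_.solve(np.full(mesh.n_triangles, SIGMA), 0.0)
    assert not field.V.any() and not field.q_rf.any() and field.power == 0.0


def test_nonpositive_sigma_rejected():
    mesh, sys_ = annulus_system(8, 4)
    sigma = np.full(mesh.n_triangles, SIGMA)
    sigma[3] = 0.0
    with pytest.raises(ValueError, match="conductivity"):
        sys_.solve(sigma, V0)
    with pytest.raises(ValueError, match="voltage"):
        sys_.solve(np.full(mesh.n_triangles, SIGMA), -1.0)


def test_scenario_solve_obeys_maximum_principle(mesh_a_medium, registry):
    sys_, arrays = scenario_electric_system(mesh_a_medium, registry)
    sigma = arrays.sigma(np.full(len(arrays.sigma0), 37.0))
    field = sys_.solve(sigma, 50.0)
    assert field.V.min() >= -1e-9
    assert field.V.max() <= 50.0 + 1e-9
    assert (field.q_rf >= 0).all()
    # metal interior carries the electrode potential, outer rim is grounded
    assert field.V[sys_.electrode_mask].min() == pytest.approx(50.0)
    assert np.abs(field.V[sys_.ground_mask]).max() == 0.0
    assert field.power > 0.0
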