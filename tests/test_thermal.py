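"""Thermal integrator: steady state, analytic eigenmode decay, per-step
energy conservation, tip sensor placement."""

import numpy as np
import pytest
from scipy.special import j0, jn_zeros

from ooablate.electric import scenario_electric_system
from ooablate.meshing import structured_rectangle_mesh
from ooablate.oracles import cylinder_decay_constant
from ooablate.thermal import ThermalProblem, find_tip_node
from ooablate.tissues import ModelConstants, TissueProperties, TissueRegistry


def _gel_registry(k=0.5, rho=1000.0, c=3600.0):
    """Single synthetic conduction-only material with constant properties."""
    gel = TissueProperties("gel", rho=rho, sigma0=0.3, c=c, k0=k, omega=0.0, water_fraction=0.0)
    return TissueRegistry({"gel": gel}, ModelConstants(d_k=0.0))


def _cylinder_problem(nr=40, nz=60, R=5e-3, H=10e-3):
    mesh = structured_rectangle_mesh(0.0, R, 0.0, H, nr, nz, label="gel")
    dirichlet = np.unique(
        np.concatenate([
            mesh.boundary_edges["rmax"].ravel(),
            mesh.boundary_edges["zmin"].ravel(),
            mesh.boundary_edges["zmax"].ravel(),
        ])
    )
    problem = ThermalProblem(
        mesh, _gel_registry(), boundary_temperature=37.0, dirichlet_nodes=dirichlet
    )
    return mesh, problem


def test_uniform_body_temperature_is_a_steady_state(mesh_a_medium, registry):
    problem = ThermalProblem(mesh_a_medium, registry)
    T = problem.initial_state(37.0)
    q = np.zeros(mesh_a_medium.n_triangles)
    alive = np.ones(mesh_a_medium.n_triangles, bool)
    T1 = problem.step(T, q, alive, dt=1.0)
    assert np.abs(T1 - 37.0).max() < 1e-9


def test_fundamental_eigenmode_decays_at_the_analytic_rate():
    R, H = 5e-3, 10e-3
    mesh, problem = _cylinder_problem(R=R, H=H)
    gel = _gel_registry().tissues["gel"]
    alpha = gel.k0 / (gel.rho * gel.c)
    lam_exact = cylinder_decay_constant(R, H, alpha)
    j01 = jn_zeros(0, 1)[0]
    r, z = mesh.nodes[:, 0], mesh.nodes[:, 1]
    T = 37.0 + 1.0 * j0(j01 * r / R) * np.sin(np.pi * z / H)
    q = np.zeros(mesh.n_triangles)
    alive = np.ones(mesh.n_triangles, bool)
    dt, nsteps = 0.05, 200
    amp0 = None
    for i in range(nsteps):
        T = problem.step(T, q, alive, dt)
        if i == 19:
            amp0 = np.abs(T - 37.0).max()
    amp1 = np.abs(T - 37.0).max()
    lam_num = np.log(amp0 / amp1) / ((nsteps - 20) * dt)
    assert lam_num == pytest.approx(lam_exact, rel=0.01)


def test_step_energy_balance_below_vaporization(mesh_a_medium, registry):
    """Lumped enthalpy change = dt * (RF power - perfusion loss + boundary
    influx) to < 1 % for a strongly heated implicit step."""
    esys, earrays = scenario_electric_system(mesh_a_medium, registry)
    problem = ThermalProblem(mesh_a_medium, registry)
    T = problem.initial_state(37.0)
    alive = np.ones(mesh_a_medium.n_triangles, bool)
    for V in (40.0, 40.0, 35.0):
        sigma = earrays.sigma(esys.elem.element_mean(T))
        q = esys.solve(sigma, V).q_rf_full
        T = problem.step(T, q, alive, dt=0.25, balance=True)
        info = problem.last_info
        assert info.rf_power > 0
        assert info.balance_residual < 0.01
    assert T.max() < 100.0


def test_undershoot_guard_and_dt_validation(mesh_a_medium, registry):
    problem = ThermalProblem(mesh_a_medium, registry)
    T = problem.initial_state(37.0)
    with pytest.raises(ValueError, match="dt"):
        problem.step(T, np.zeros(mesh_a_medium.n_triangles), np.ones(mesh_a_medium.n_triangles, bool), dt=0.0)


def test_tip_sensor_sits_at_the_distal_apex(mesh_a_coarse):
    node = find_tip_node(mesh_a_coarse)
    r, z = mesh_a_coarse.nodes[node] * 1e3
    el = mesh_a_coarse.geometry.electrode
    assert abs(r) < 0.25
    assert abs(z - el.tip_bottom) < 0.25
    # the apex node belongs to the active-tip interface
    tip_nodes = set(mesh_a_coarse.boundary_edges["electrode_active_tip"].ravel().tolist())
    assert node in tip_nodes


def test_validation_scenario_starts_at_35(validation_run):
    assert validation_run.tip_temperature[0] == pytest.approx(35.0)
    assert validation_run.probe_temperatures[0] == pytest.approx([35.0, 35.0, 35.0])
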