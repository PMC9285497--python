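"""Shared fixtures: meshes and closed-loop runs reused across test modules.

The heavy closed-loop simulations are session-scoped and scaled down
(coarser meshes and/or shorter procedures than the full study) so the
whole suite stays fast; the full-scale runs appear only where a check is
explicitly about full-procedure behaviour.
"""

from __future__ import annotations

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from ooablate import SimulationConfig, TissueRegistry, run_simulation
from ooablate.geometry import build_scenario
from ooablate.meshing import generate_mesh

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry() -> TissueRegistry:
    return TissueRegistry.default()


@pytest.fixture(scope="session")
def geom_a():
    return build_scenario("a")


@pytest.fixture(scope="session")
def mesh_a_coarse(geom_a):
    return generate_mesh(geom_a, "coarse")


@pytest.fixture(scope="session")
def mesh_a_medium(geom_a):
    return generate_mesh(geom_a, "medium")


@pytest.fixture(scope="session")
def run_a90_fine_full():
    """Full-procedure run of the sclerosis scenario at 90 °C: 15 min
    heating + 5 min cooldown on the default (fine) mesh."""
    cfg = SimulationConfig(
        scenario_id="a", control_temperature=90.0, heat_duration=900.0,
        cool_duration=300.0, resolution="fine",
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def run_b70_fine_full():
    """Weakest tested configuration: trabecular scenario at 70 °C."""
    cfg = SimulationConfig(
        scenario_id="b", control_temperature=70.0, heat_duration=900.0,
        cool_duration=300.0, resolution="fine",
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def run_c90_medium_full():
    """Full-procedure intracortical run at 90 °C (medium mesh)."""
    cfg = SimulationConfig(
        scenario_id="c", control_temperature=90.0, heat_duration=900.0,
        cool_duration=300.0, resolution="medium",
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def mini_grid():
    """Scenario × control-temperature grid on scaled-down runs
    (coarse mesh, 5 min heating + 1 min cooldown)."""
    from ooablate.experiments import run_temperature_time_grid

    base = SimulationConfig(heat_duration=300.0, cool_duration=60.0, resolution="coarse")
    results, table = run_temperature_time_grid(("a", "b", "c"), (70.0, 80.0, 90.0), base)
    for key, value in results.items():
        assert not isinstance(value, Exception), f"grid cell {key} failed: {value}"
    return results, table


@pytest.fixture(scope="session")
def run_a90_medium_short():
    """Scaled-down baseline for the discretization-robustness checks."""
    cfg = SimulationConfig(
        scenario_id="a", control_temperature=90.0, heat_duration=300.0,
        cool_duration=60.0, resolution="medium",
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def sensitivity_table_scaled():
    """Nidus conductivity sweep at baseline perfusion (medium mesh,
    doubled heating step, full 15 + 5 min procedure)."""
    from ooablate.experiments import run_sensitivity

    cfg = SimulationConfig(
        scenario_id="a", control_temperature=90.0, heat_duration=900.0,
        cool_duration=300.0, resolution="medium", dt_heat=0.5,
    )
    return run_sensitivity(cfg, sigma_values=(0.08, 0.5), omega_values=(48e-4,))


@pytest.fixture(scope="session")
def convergence_pair():
    """Perpendicular radius on the two finest ladder levels for a 3-min
    scaled-down run of scenario a at 90 °C."""
    base = SimulationConfig(
        scenario_id="a", control_temperature=90.0, heat_duration=180.0,
        cool_duration=120.0,
    )
    geom = build_scenario("a")
    out = {}
    for lvl in ("fine", "finest"):
        mesh = generate_mesh(geom, lvl)
        res = run_simulation(replace(base, resolution=lvl), mesh=mesh)
        out[lvl] = res.final_radius("perpendicular")
    return out


@pytest.fixture(scope="session")
def validation_run():
    """Ex-vivo bench run (3 mm lamella): 400 s at 95 °C from 35 °C."""
    from ooablate.experiments import run_validation_scenario

    base = SimulationConfig(cool_duration=60.0, resolution="medium")
    return run_validation_scenario(base_config=base)
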