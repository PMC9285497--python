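"""Closed-loop ablation simulation: controller + electric + thermal + damage.

One simulated procedure is: PI-controlled active heating at the chosen
control temperature (the quasi-static electric problem is re-solved every
thermal step with sigma(T)), followed by a passive cooldown with the
generator off during which heat keeps diffusing and thermal damage keeps
accruing.  Per step the coupling order is: read tip temperature -> update
the controller voltage -> electric solve -> implicit thermal step ->
Arrhenius damage update (which gates perfusion for the next step).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .control import PIController
from .damage import (
    OMEGA_DEATH,
    RadiusExtractor,
    RadiusSeries,
    integrate_damage,
    update_alive,
)
from .electric import scenario_electric_system
from .geometry import RegionGeometry, build_scenario
from .meshing import Mesh, generate_mesh, probe_indices
from .thermal import ThermalProblem, find_tip_node
from .tissues import TissueRegistry

__all__ = ["SimulationConfig", "AblationResult", "run_simulation"]


@dataclass
class SimulationConfig:
    """Inputs of one simulated procedure (times in s, temperatures in °C)."""

    scenario_id: str = "a"
    control_temperature: float = 90.0
    heat_duration: float = 900.0
    cool_duration: float = 300.0
    resolution: str = "fine"
    dt_heat: float = 0.25
    dt_cool: float = 1.0
    kp: float = 1.15  # V/K
    ki: float = 0.06  # V/(K s)
    geometry_overrides: dict[str, float] = field(default_factory=dict)
    property_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    output_interval: float = 5.0
    sample_mm: float = 0.05
    picard_tol: float = 1e-3
    picard_max: int = 5
    radius_threshold: float = OMEGA_DEATH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heat_duration < 0 or self.cool_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.heat_duration + self.cool_duration <= 0:
            raise ValueError("simulation must run for a positive time")
        if not self.control_temperature < 100.0:
            raise ValueError("control temperature must be below 100 °C")
        if self.dt_heat <= 0 or self.dt_cool <= 0:
            raise ValueError("time steps must be positive")


@dataclass
class AblationResult:
    """Outputs of one simulated procedure."""

    config: SimulationConfig
    mesh: Mesh
    radii: RadiusSeries
    times: np.ndarray  # s, output cadence
    voltage: np.ndarray  # V r.m.s.
    tip_temperature: np.ndarray  # °C
    max_temperature: np.ndarray  # °C, running per-sample nodal max
    final_T: np.ndarray
    final_omega: np.ndarray
    snapshots: dict[str, dict[str, Any]]
    probe_temperatures: np.ndarray | None  # (samples, n_probes), °C
    peak_temperature: float  # max nodal T over every step
    provenance: dict[str, Any]

    def final_radius(self, direction: str = "perpendicular") -> float:
        series = getattr(self.radii, direction)
        return float(series[-1])

    def timeseries(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "voltage_Vrms": self.voltage,
                "tip_temperature_C": self.tip_temperature,
                "max_temperature_C": self.max_temperature,
                "radius_perpendicular_mm": self.radii.perpendicular,
                "radius_parallel_mm": self.radii.parallel,
            }
        )
        if self.probe_temperatures is not None:
            for j in range(self.probe_temperatures.shape[1]):
                df[f"probe{j}_temperature_C"] = self.probe_temperatures[:, j]
        return df


def run_simulation(
    config: SimulationConfig,
    mesh: Mesh | None = None,
    geometry: RegionGeometry | None = None,
    registry: TissueRegistry | None = None,
) -> AblationResult:
    """Run one closed-loop procedure; deterministic for a fixed config.

    A prebuilt ``mesh`` (and its geometry) may be passed to amortize
    meshing across runs that differ only in tissue properties, control
    temperature or timing.
    """
    if geometry is None:
        geometry = mesh.geometry if mesh is not None else build_scenario(
            config.scenario_id, config.geometry_overrides
        )
    if mesh is None:
        mesh = generate_mesh(geometry, config.resolution, seed=config.seed)

    if registry is None:
        registry = TissueRegistry.default()
    registry = registry.with_overrides(config.property_overrides)
    if geometry.ex_vivo:
        registry = registry.zero_perfusion()

    esys, earrays = scenario_electric_system(mesh, registry)
    thermal = ThermalProblem(
        mesh,
        registry,
        boundary_temperature=geometry.initial_temperature,
        picard_tol=config.picard_tol,
        picard_max=config.picard_max,
    )
    tip = find_tip_node(mesh)
    extractor = RadiusExtractor(mesh, config.sample_mm)
    controller = PIController(config.control_temperature, config.kp, config.ki)
    probes = (
        probe_indices(mesh, geometry.probe_points) if geometry.probe_points else None
    )

    T = thermal.initial_state(geometry.initial_temperature)
    omega = np.zeros(mesh.n_nodes)
    alive = np.ones(mesh.n_triangles, dtype=bool)
    q_zero = np.zeros(mesh.n_triangles)

    times, volts, tips, maxs = [], [], [], []
    radii = RadiusSeries()
    probe_rows: list[np.ndarray] = []
    snapshots: dict[str, dict[str, Any]] = {}
    peak_T = float(T.max())

    def record(t: float, V: float) -> None:
        times.append(t)
        volts.append(V)
        tips.append(float(T[tip]))
        maxs.append(float(T.max()))
        radii.append(
            t,
            extractor.radius(omega, "perpendicular", config.radius_threshold),
            extractor.radius(omega, "parallel", config.radius_threshold),
        )
        if probes is not None:
            probe_rows.append(T[probes].copy())

    def snap(name: str, t: float, q_full: np.ndarray) -> None:
        snapshots[name] = {
            "time_s": t,
            "T": T.copy(),
            "omega": omega.copy(),
            "q_rf": q_full.copy(),
        }

    record(0.0, 0.0)
    n_heat = int(round(config.heat_duration / config.dt_heat))
    n_cool = int(round(config.cool_duration / config.dt_cool))
    t = 0.0
    next_out = config.output_interval
    early_snapped = False
    q_full = q_zero

    for phase, n_steps, dt in (("heat", n_heat, config.dt_heat), ("cool", n_cool, config.dt_cool)):
        if phase == "cool":
            controller.cooldown_mode()
        for _ in range(n_steps):
            V = controller.update(float(T[tip]), dt)
            if V > 0.0:
                sigma_e = earrays.sigma(esys.elem.element_mean(T))
                fieldV = esys.solve(sigma_e, V)
                q_full = fieldV.q_rf_full
            else:
                q_full = q_zero
            T_new = thermal.step(T, q_full, alive, dt)
            omega = integrate_damage(omega, T, T_new, dt)
            alive = update_alive(alive, omega, mesh.triangles, config.radius_threshold)
            T = T_new
            peak_T = max(peak_T, float(T.max()))
            t += dt
            if t >= next_out - 1e-9:
                record(t, V)
                next_out += config.output_interval
            if phase == "heat" and not early_snapped and t >= 30.0 - 1e-9:
                snap("early", t, q_full)
                early_snapped = True
        if phase == "heat":
            if times[-1] < t - 1e-9:
                record(t, volts[-1] if n_heat else 0.0)
            snap("end_heat", t, q_full)
            if not early_snapped:
                snap("early", t, q_full)
                early_snapped = True
    if times[-1] < t - 1e-9:
        record(t, 0.0)
    snap("end_cool", t, q_zero)

    provenance = {
        "package_version": __version__,
        "mesh_nodes": mesh.n_nodes,
        "mesh_triangles": mesh.n_triangles,
        "mesh_level": mesh.level,
        "seed": config.seed,
        "config": asdict(config),
    }
    return AblationResult(
        config=config,
        mesh=mesh,
        radii=radii,
        times=np.asarray(times),
        voltage=np.asarray(volts),
        tip_temperature=np.asarray(tips),
        max_temperature=np.asarray(maxs),
        final_T=T,
        final_omega=omega,
        snapshots=snapshots,
        probe_temperatures=np.asarray(probe_rows) if probe_rows else None,
        peak_temperature=peak_T,
        provenance=provenance,
    )
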