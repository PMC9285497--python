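"""Enthalpy-form bioheat time integration.

Solves ``dh/dt = div(k(T) grad T) + Q_RF - Qp`` with backward-Euler steps
on the axisymmetric P1 mesh.  The enthalpy nonlinearity (latent ramp over
99–100 °C) is handled with a Newton-like Picard linearization: per
iteration the apparent volumetric heat capacity is evaluated per element
at the mean nodal temperature and the residual enthalpy difference is
carried on the right-hand side, so the converged step conserves energy in
the enthalpy sense.  Mass and perfusion terms are lumped (one third of
the element volume per node).

Boundary conditions: fixed body-core temperature on the outer boundary,
natural zero flux on the symmetry axis.  The electrode metal and plastic
stay in the thermal solve (they conduct heat) with zero internal Q_RF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import DirichletSystem, ElementData
from .meshing import Mesh
from .tissues import TissueRegistry, _capacity, _enthalpy

__all__ = ["ThermalProblem", "find_tip_node"]


@dataclass
class StepInfo:
    """Diagnostics of one backward-Euler step."""

    picard_iterations: int
    max_dT: float  # last Picard increment, °C
    enthalpy_rate: float = np.nan  # W, d/dt of total enthalpy
    rf_power: float = np.nan  # W
    perfusion_power: float = np.nan  # W
    boundary_influx: float = np.nan  # W, conduction through Dirichlet set

    @property
    def balance_residual(self) -> float:
        """Relative energy-balance defect of the step."""
        lhs = self.enthalpy_rate
        rhs = self.rf_power - self.perfusion_power + self.boundary_influx
        scale = max(abs(lhs), abs(rhs), 1e-12)
        return abs(lhs - rhs) / scale


class ThermalProblem:
    """Backward-Euler integrator of the enthalpy bioheat equation."""

    def __init__(
        self,
        mesh: Mesh,
        registry: TissueRegistry | None = None,
        boundary_temperature: float = 37.0,
        dirichlet_nodes: np.ndarray | None = None,
        picard_tol: float = 1e-3,
        picard_max: int = 5,
    ):
        self.mesh = mesh
        self.registry = registry or TissueRegistry.default()
        self.elem = ElementData(mesh)
        self.arrays = self.registry.arrays_for(mesh.labels)
        self.constants = self.registry.constants
        self.boundary_temperature = float(boundary_temperature)
        if dirichlet_nodes is None:
            outer = mesh.boundary_edges["outer_boundary"]
            dirichlet_nodes = np.unique(outer)
        mask = np.zeros(mesh.n_nodes, dtype=bool)
        mask[dirichlet_nodes] = True
        self.system = DirichletSystem(self.elem, mask)
        self.dirichlet_values = np.full(mesh.n_nodes, self.boundary_temperature)
        self.picard_tol = float(picard_tol)
        self.picard_max = int(picard_max)
        # perfusion volumetric coefficient per element, W/(m^3 K), before
        # viability gating
        self.perf_base = (
            self.arrays.omega * self.constants.rho_blood * self.constants.c_blood
        )
        self.last_info: StepInfo | None = None
        self._floor = self.boundary_temperature  # refined by initial state

    def initial_state(self, T0: float | None = None) -> np.ndarray:
        T0 = self.boundary_temperature if T0 is None else float(T0)
        self._floor = min(self.boundary_temperature, T0)
        return np.full(self.mesh.n_nodes, T0)

    def _h_nodal(self, T: np.ndarray) -> np.ndarray:
        """Enthalpy at each element's nodes with that element's material."""
        a = self.arrays
        return _enthalpy(
            a.rho[:, None],
            a.c[:, None],
            a.water_fraction[:, None],
            T[self.elem.tris],
            self.constants,
        )

    def total_enthalpy(self, T: np.ndarray) -> float:
        """Lumped total enthalpy of the domain (J, relative to 37 °C)."""
        w = self.elem.volume[:, None] / 3.0
        return float((self._h_nodal(T) * w).sum())

    def step(
        self,
        T_old: np.ndarray,
        q_rf_full: np.ndarray,
        alive: np.ndarray,
        dt: float,
        balance: bool = False,
    ) -> np.ndarray:
        """Advance one backward-Euler step of length ``dt`` seconds.

        ``q_rf_full`` is the per-element Joule source (W/m^3, zero in the
        metal); ``alive`` the per-element viability mask gating perfusion.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        elem, sysd = self.elem, self.system
        tris = elem.tris
        n = self.mesh.n_nodes
        vol3 = elem.volume / 3.0
        pc_e = self.perf_base * alive  # W/(m^3 K)
        h_old = self._h_nodal(T_old)
        src = elem.lump_source(q_rf_full + pc_e * self.constants.T_blood)

        T_old_n = T_old[tris]
        a = self.arrays
        T_star = T_old.copy()
        prev_dT = np.inf
        for it in range(1, self.picard_max + 1):
            Tm = elem.element_mean(T_star)
            k_e = self.arrays.k(Tm)
            # chord (secant) apparent capacity per element-node pair, exactly
            # consistent with the nodal enthalpy residual on the right-hand
            # side: a node inside the latent ramp then carries the full
            # latent capacity on the diagonal (stable across 99-100 °C)
            T_star_n = T_star[tris]
            h_star = self._h_nodal(T_star)
            dTn = T_star_n - T_old_n
            C_tan = _capacity_pn(a, T_star_n, self.constants)
            with np.errstate(divide="ignore", invalid="ignore"):
                C_chord = (h_star - h_old) / dTn
            C_pn = np.where(np.abs(dTn) > 1e-8, C_chord, C_tan)
            data = elem.assemble_values(k_e)
            diag = np.bincount(
                tris.ravel(),
                weights=((C_pn / dt + pc_e[:, None]) * vol3[:, None]).ravel(),
                minlength=n,
            )
            data_full = sysd.add_diagonal(data, diag)
            mass = (C_pn / dt) * T_star_n - (h_star - h_old) / dt
            rhs = src + np.bincount(
                tris.ravel(), weights=(mass * vol3[:, None]).ravel(), minlength=n
            )
            T_new = sysd.solve(data_full, rhs, self.dirichlet_values)
            max_dT = float(np.abs(T_new - T_star).max())
            if not np.isfinite(max_dT):
                raise FloatingPointError("thermal step produced non-finite T")
            if max_dT > 2.0 * prev_dT and max_dT > 50.0:
                raise RuntimeError(
                    f"Picard divergence: increment grew to {max_dT:.2f} °C "
                    f"(step dt={dt}, iteration {it})"
                )
            T_prev_star = T_star
            if max_dT > prev_dT and it > 1:
                # damp an oscillating iteration (latent-ramp crossings)
                T_star = 0.5 * (T_new + T_star)
            else:
                T_star = T_new
            if max_dT < self.picard_tol:
                T_star = T_new
                break
            prev_dT = max_dT

        if T_new.min() < self._floor - 0.5:
            raise RuntimeError(
                f"spurious temperature undershoot: min T = {T_new.min():.3f} °C"
            )

        info = StepInfo(picard_iterations=it, max_dT=max_dT)
        if balance:
            # enthalpy as the solver saw it: linearized about the last iterate
            h_lin = h_star + C_pn * (T_new[tris] - T_prev_star[tris])
            dH = float(((h_lin - h_old) * vol3[:, None]).sum())
            info.enthalpy_rate = dH / dt
            info.rf_power = elem.integrate(q_rf_full)
            q_perf = pc_e * (elem.element_mean(T_new) - self.constants.T_blood)
            info.perfusion_power = elem.integrate(q_perf)
            reac = sysd.reactions(data_full, T_new, rhs)
            info.boundary_influx = float(reac.sum())
        self.last_info = info
        return T_new


def _capacity_pn(arrays, T_n, mc):
    """Tangent apparent capacity at each element's nodes (element material)."""
    return _capacity(
        arrays.rho[:, None], arrays.c[:, None], arrays.water_fraction[:, None], T_n, mc
    )


def find_tip_node(mesh: Mesh) -> int:
    """Index of the controller's temperature sensor node: the node at the
    distal apex of the active tip on the symmetry axis."""
    if mesh.geometry is None:
        raise ValueError("mesh carries no scenario geometry")
    target = np.array([0.0, mesh.geometry.electrode.tip_bottom * 1e-3])
    d = np.hypot(*(mesh.nodes - target).T)
    return int(np.argmin(d))
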