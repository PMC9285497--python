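"""Quasi-static electric problem and Joule heating.

At RF ablation frequencies (~500 kHz) the tissue is effectively resistive,
so the potential obeys the generalized Laplace equation
``div(sigma(T) grad V) = 0`` with the r.m.s. electrode voltage applied on
the conducting active tip, ground (0 V) on the outer boundary and a
natural zero-flux condition on the symmetry axis.  The electrode metal is
excluded from the solve (it is an equipotential Dirichlet region); the
plastic insulation stays in with its very small conductivity.

The resistive heat source is ``Q_RF = sigma |grad V|^2`` per element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import DirichletSystem, ElementData
from .meshing import Mesh
from .tissues import TissueRegistry

__all__ = ["PotentialField", "ElectricSystem", "scenario_electric_system"]


@dataclass
class PotentialField:
    """Solved potential and derived fields.

    ``V`` is nodal (volts, r.m.s.); ``E_mag`` and ``q_rf`` are per solved
    element; ``q_rf_full`` maps the source back onto the full element list
    (zero inside the excluded electrode metal).
    """

    V: np.ndarray
    E_mag: np.ndarray
    q_rf: np.ndarray
    q_rf_full: np.ndarray
    sigma: np.ndarray
    voltage: float
    power: float  # total delivered power, W


class ElectricSystem:
    """Reusable electric solver on a fixed mesh and Dirichlet layout."""

    def __init__(
        self,
        mesh: Mesh,
        electrode_nodes: np.ndarray,
        ground_nodes: np.ndarray,
        element_mask: np.ndarray | None = None,
    ):
        self.mesh = mesh
        self.elem = ElementData(mesh, element_mask)
        n = mesh.n_nodes
        self.electrode_mask = np.zeros(n, dtype=bool)
        self.electrode_mask[electrode_nodes] = True
        ground_mask = np.zeros(n, dtype=bool)
        ground_mask[ground_nodes] = True
        ground_mask &= ~self.electrode_mask
        self.ground_mask = ground_mask
        self.system = DirichletSystem(self.elem, self.electrode_mask | ground_mask)
        if element_mask is None:
            self.full_index = np.arange(mesh.n_triangles)
        else:
            self.full_index = np.flatnonzero(element_mask)
        self.n_full = mesh.n_triangles

    def assemble(self, sigma_e: np.ndarray) -> np.ndarray:
        """Stiffness data for per-element conductivity (must be > 0)."""
        sigma_e = np.asarray(sigma_e, dtype=float)
        if sigma_e.shape != self.elem.volume.shape:
            raise ValueError("sigma must be given per solved element")
        if not (sigma_e > 0).all():
            raise ValueError("non-positive electrical conductivity")
        return self.elem.assemble_values(sigma_e)

    def solve(
        self, sigma_e: np.ndarray, voltage: float, outer_voltage: float = 0.0
    ) -> PotentialField:
        """Solve the potential and evaluate |E| and Q_RF per element."""
        if voltage < 0:
            raise ValueError("electrode voltage must be >= 0")
        n = self.mesh.n_nodes
        if voltage == 0.0 and outer_voltage == 0.0:
            V = np.zeros(n)
            z = np.zeros(len(self.elem.volume))
            return PotentialField(V, z, z.copy(), np.zeros(self.n_full), sigma_e, 0.0, 0.0)
        data = self.assemble(sigma_e)
        dval = np.zeros(n)
        dval[self.electrode_mask] = voltage
        dval[self.ground_mask] = outer_voltage
        V = self.system.solve(data, np.zeros(n), dval)
        grad = np.einsum("mi,mik->mk", V[self.elem.tris], self.elem.grad)
        e2 = (grad**2).sum(axis=1)
        q = sigma_e * e2
        q_full = np.zeros(self.n_full)
        q_full[self.full_index] = q
        power = float(np.dot(q, self.elem.volume))
        return PotentialField(V, np.sqrt(e2), q, q_full, sigma_e, voltage, power)

    def delivered_power(self, field: PotentialField) -> float:
        """Total Joule power, volume integral of Q_RF (watts)."""
        return float(np.dot(field.q_rf, self.elem.volume))


def scenario_electric_system(mesh: Mesh, registry: TissueRegistry | None = None):
    """Electric system for a scenario mesh: metal excluded and held at the
    applied voltage, outer boundary grounded.

    Returns ``(system, tissue_arrays)`` where the arrays are per solved
    element (for evaluating sigma(T) each step).
    """
    registry = registry or TissueRegistry.default()
    mask = mesh.labels != "electrode"
    metal_nodes = np.unique(mesh.triangles[~mask])
    outer = mesh.boundary_edges["outer_boundary"]
    ground_nodes = np.unique(outer) if len(outer) else np.empty(0, np.int64)
    system = ElectricSystem(mesh, metal_nodes, ground_nodes, element_mask=mask)
    arrays = registry.arrays_for(mesh.labels[mask])
    return system, arrays
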