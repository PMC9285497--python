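"""Arrhenius thermal-damage model and cell-death radius extraction.

Cumulative damage at every node follows the first-order Arrhenius
integral ``Omega(t) = int A exp(-dE / (R T(tau))) dtau`` with the
osteocyte kinetics A = 8.99e133 1/s and dE = 838 kJ/mol; the rate is
always evaluated in log space (ln A - dE/RT, then exponentiated), since A
overflows any naive double-precision product chain.  ``Omega >= 4.6``
marks cell death (1 - exp(-4.6) ≈ 99 % death probability); a dead
element's blood perfusion is switched off permanently.

The ablation extent is reported as the outermost ``Omega = 4.6`` crossing
along two rays from the active-tip centre: perpendicular to the electrode
(+r) and parallel to it (upwards).  Because the symmetry axis above the
tip lies inside the electrode shaft, the parallel ray runs along the
outside of the shaft insulation and reports the axial distance from the
tip centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import LinearTriInterpolator, TrapezoidMapTriFinder, Triangulation
from scipy.constants import R as GAS_CONSTANT

from .meshing import Mesh

__all__ = [
    "ARRHENIUS_A",
    "ARRHENIUS_DE",
    "OMEGA_DEATH",
    "arrhenius_rate",
    "integrate_damage",
    "death_probability",
    "update_alive",
    "RadiusExtractor",
    "RadiusSeries",
]

ARRHENIUS_A = 8.99e133  # 1/s (osteocyte frequency factor)
ARRHENIUS_DE = 838e3  # J/mol (activation energy)
OMEGA_DEATH = 4.6  # 99 % probability of cell death
_LN_A = np.log(8.99) + 133.0 * np.log(10.0)


def arrhenius_rate(T_kelvin):
    """Damage accumulation rate A*exp(-dE/(R T)) in 1/s (log-space eval)."""
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    out = np.exp(_LN_A - ARRHENIUS_DE / (GAS_CONSTANT * T))
    return out if out.ndim else float(out)


def integrate_damage(omega, T_old_C, T_new_C, dt):
    """Accumulate ``omega += dt * rate(Tbar)`` with the trapezoidal mean of
    the endpoint temperatures (°C in, converted to kelvin)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    Tbar = 0.5 * (np.asarray(T_old_C, float) + np.asarray(T_new_C, float)) + 273.15
    return omega + dt * arrhenius_rate(Tbar)


def death_probability(omega):
    """Probability of cell death 1 - exp(-Omega)."""
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ValueError("Omega must be non-negative")
    out = -np.expm1(-om)
    return out if out.ndim else float(out)


def update_alive(alive, omega_nodal, triangles, threshold: float = OMEGA_DEATH):
    """One-way viability update: an element dies (and never revives) when
    its mean nodal damage reaches the threshold."""
    dead = omega_nodal[triangles].mean(axis=1) >= threshold
    return alive & ~dead


@dataclass
class RadiusSeries:
    """Cell-death radii versus time (mm, from the active-tip centre)."""

    times: list[float] = field(default_factory=list)
    perpendicular: list[float] = field(default_factory=list)
    parallel: list[float] = field(default_factory=list)

    def append(self, t: float, r_perp: float, r_par: float) -> None:
        self.times.append(t)
        self.perpendicular.append(r_perp)
        self.parallel.append(r_par)


class RadiusExtractor:
    """Samples a nodal field along the measurement rays of a scenario mesh.

    The perpendicular ray is z = 0, r from the axis to the domain edge;
    the parallel ray hugs the outside of the shaft insulation (r = shaft
    outer radius + one sample step) and runs upwards.  The reported radius
    is the outermost linear crossing of the threshold.
    """

    def __init__(self, mesh: Mesh, sample_mm: float = 0.05):
        if mesh.geometry is None:
            raise ValueError("mesh carries no scenario geometry")
        g = mesh.geometry
        self.tri = Triangulation(
            mesh.nodes[:, 0], mesh.nodes[:, 1], triangles=mesh.triangles
        )
        self.tri._trifinder = TrapezoidMapTriFinder(self.tri)
        step = sample_mm * 1e-3
        eps = 0.5 * step
        rmax, zmax = g.r_max * 1e-3, g.z_max * 1e-3
        r_line = g.electrode.outer_radius * 1e-3 + step
        perp_r = np.arange(0.0, rmax - eps, step)
        par_z = np.arange(0.0, zmax - eps, step)
        self._rays = {
            "perpendicular": (perp_r, np.zeros_like(perp_r), perp_r),
            "parallel": (np.full_like(par_z, r_line), par_z, par_z),
        }

    def sample(self, nodal_field: np.ndarray, direction: str):
        """(distances_mm, values) of the field along a measurement ray."""
        try:
            xs, ys, dist = self._rays[direction]
        except KeyError:
            raise ValueError(
                f"direction must be 'perpendicular' or 'parallel', got {direction!r}"
            ) from None
        interp = LinearTriInterpolator(self.tri, nodal_field)
        vals = interp(xs, ys)
        return dist * 1e3, np.ma.filled(vals, np.nan)

    def sample_element_field(self, per_element: np.ndarray, direction: str):
        """(distances_mm, values) of a piecewise-constant per-element field
        (e.g. Q_RF) along a measurement ray."""
        try:
            xs, ys, dist = self._rays[direction]
        except KeyError:
            raise ValueError(
                f"direction must be 'perpendicular' or 'parallel', got {direction!r}"
            ) from None
        tri_idx = self.tri._trifinder(xs, ys)
        vals = np.where(tri_idx >= 0, per_element[np.maximum(tri_idx, 0)], np.nan)
        return dist * 1e3, vals

    def radius(
        self, omega_nodal: np.ndarray, direction: str, threshold: float = OMEGA_DEATH
    ) -> float:
        """Outermost threshold crossing along the ray, mm (0 if none).

        The damage field decays near-exponentially away from the electrode,
        so the nodal field is reconstructed in log space (linear elements on
        log Omega); interpolating Omega itself would overshoot by orders of
        magnitude across far-field elements.
        """
        log_omega = np.log(np.maximum(omega_nodal, 1e-30))
        dist, vals = self.sample(log_omega, direction)
        ok = np.isfinite(vals)
        dist, vals = dist[ok], vals[ok]
        if len(dist) == 0:
            raise RuntimeError(f"ray {direction!r} has no samples inside the domain")
        thr = np.log(threshold)
        above = vals >= thr
        if not above.any():
            return 0.0
        i = int(np.flatnonzero(above).max())
        if i == len(dist) - 1:
            return float(dist[i])
        v0, v1 = vals[i], vals[i + 1]
        frac = (v0 - thr) / max(v0 - v1, 1e-300)
        return float(dist[i] + frac * (dist[i + 1] - dist[i]))
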