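"""Independent verification oracles for the solver numerics.

Closed-form or brute-force references that share no code with the solver
paths they certify:

* concentric-cylinder (annulus) potential and conductance for the
  axisymmetric Laplace discretization;
* fundamental conduction eigenmode of a finite cylinder (first Bessel
  zero) plus a 1-D radial finite-difference eigenvalue reference;
* arbitrary-precision Arrhenius rate and fine-step quadrature of the
  damage integral (mpmath), against which the double-precision solver
  path is checked.
"""

from __future__ import annotations

import numpy as np
from scipy.constants import R as GAS_CONSTANT
from scipy.special import jn_zeros

__all__ = [
    "annulus_potential",
    "annulus_conductance",
    "cylinder_decay_constant",
    "radial_decay_constant_fd",
    "arrhenius_rate_mp",
    "arrhenius_quadrature",
    "time_to_threshold",
]


def annulus_potential(r, a: float, b: float, V0: float):
    """Potential between concentric cylinders: V(a) = V0, V(b) = 0."""
    if not 0 < a < b:
        raise ValueError("require 0 < a < b")
    r = np.asarray(r, dtype=float)
    out = V0 * np.log(b / r) / np.log(b / a)
    return out if out.ndim else float(out)


def annulus_conductance(sigma: float, L: float, a: float, b: float) -> float:
    """Conductance of the annular resistor, G = 2 pi sigma L / ln(b/a)."""
    if not 0 < a < b:
        raise ValueError("require 0 < a < b")
    return 2.0 * np.pi * sigma * L / np.log(b / a)


def cylinder_decay_constant(radius: float, height: float, diffusivity: float) -> float:
    """Fundamental decay rate (1/s) of conduction in a finite cylinder with
    a cold (Dirichlet) boundary: alpha * (j01^2/R^2 + pi^2/H^2)."""
    j01 = float(jn_zeros(0, 1)[0])
    return diffusivity * (j01**2 / radius**2 + np.pi**2 / height**2)


def radial_decay_constant_fd(radius: float, diffusivity: float, n: int = 4000) -> float:
    """Radial part of the decay constant from an independent 1-D
    finite-difference eigensolver (cell-centred, Dirichlet at r = R)."""
    from scipy.linalg import eigh_tridiagonal

    dr = radius / n
    r = (np.arange(n) + 0.5) * dr
    r_plus = r + 0.5 * dr
    r_minus = r - 0.5 * dr
    diag = (r_plus + r_minus) / (r * dr**2)
    # regularity at the axis: r_minus[0] = 0 drops the inner flux naturally
    diag[0] = r_plus[0] / (r[0] * dr**2)
    # symmetrize with D = diag(r): B = D^{1/2} A D^{-1/2}
    off = -r_plus[:-1] / (np.sqrt(r[:-1] * r[1:]) * dr**2)
    lam = eigh_tridiagonal(diag, off, select="i", select_range=(0, 0))[0][0]
    return diffusivity * float(lam)


def arrhenius_rate_mp(T_kelvin: float, A: float = 8.99e133, dE: float = 838e3) -> float:
    """Arrhenius damage rate evaluated in 50-digit arithmetic."""
    import mpmath as mp

    with mp.workdps(50):
        rate = mp.mpf(A) * mp.e ** (-mp.mpf(dE) / (mp.mpf(GAS_CONSTANT) * mp.mpf(T_kelvin)))
        return float(rate)


def arrhenius_quadrature(times, temps_C, dt_fine: float) -> float:
    """Rectangle-rule damage integral on a piecewise-linear T(t) trace,
    resampled at ``dt_fine`` with arbitrary-precision rate evaluation."""
    times = np.asarray(times, float)
    temps_C = np.asarray(temps_C, float)
    if len(times) != len(temps_C) or len(times) < 2:
        raise ValueError("need matching times/temperatures with >= 2 samples")
    t_fine = np.arange(times[0], times[-1], dt_fine)
    T_fine = np.interp(t_fine, times, temps_C) + 273.15
    return float(sum(arrhenius_rate_mp(Tk) * dt_fine for Tk in T_fine))


def time_to_threshold(T_C: float, omega: float = 4.6) -> float:
    """Closed-form time to reach a damage level at constant temperature."""
    return omega / arrhenius_rate_mp(T_C + 273.15)
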