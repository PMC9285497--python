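"""Tissue property registry and temperature-dependent material models.

Holds the per-tissue constants used throughout the electro-thermal model
(density, baseline electrical and thermal conductivity at 37 °C, specific
heat, blood-perfusion coefficient, water fraction) and the piecewise
temperature dependences:

* electrical conductivity: +1.5 %/°C of baseline up to 100 °C, then a linear
  collapse to the vaporized-tissue value ``sigma_vap`` over 100–105 °C;
* thermal conductivity: linear increase (absolute slope by default) capped
  at its 100 °C value;
* volumetric enthalpy (apparent-heat-capacity / enthalpy method): sensible
  branch, a latent ramp over 99–100 °C carrying ``rho * h_fg * C`` per unit
  volume, and a vapor branch with ``rho_vap * c_vap`` slope;
* Pennes perfusion sink ``omega * rho_b * c_b * (T - Tb)``, gated by cell
  viability (a dead cell perfuses exactly zero).

All property functions accept scalars or numpy arrays of temperature in °C
and are continuous across every branch point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "TissueProperties",
    "ModelConstants",
    "TissueRegistry",
    "TissueArrays",
]

#: Tissue names expected in the default registry (Table-order).
DEFAULT_TISSUES = (
    "electrode",
    "plastic",
    "nidus",
    "sclerotic",
    "trabecular",
    "cortical",
    "muscle",
)


@dataclass(frozen=True)
class TissueProperties:
    """Baseline (37 °C) constants of one material."""

    name: str
    rho: float  # density, kg/m^3
    sigma0: float  # electrical conductivity at 37 C, S/m
    c: float  # specific heat, J/(kg K)
    k0: float  # thermal conductivity at 37 C, W/(m K)
    omega: float  # blood perfusion coefficient, 1/s
    water_fraction: float  # dimensionless, 0..1

    def __post_init__(self) -> None:
        for f_ in ("rho", "sigma0", "c", "k0", "omega", "water_fraction"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{self.name}: {f_} must be >= 0")
        if self.water_fraction > 1:
            raise ValueError(f"{self.name}: water_fraction must be <= 1")


@dataclass(frozen=True)
class ModelConstants:
    """Global constants of the property models and the perfusion sink.

    ``d_sigma_rel`` is a relative rate (fraction of the baseline per °C);
    ``d_k`` is an absolute slope in W/(m K °C) unless ``d_k_relative`` is
    set, in which case it is a fraction of the baseline per °C.
    """

    d_sigma_rel: float = 0.015  # +1.5 %/°C of baseline
    d_k: float = 0.003  # W/(m K) per °C (absolute reading, default)
    d_k_relative: bool = False
    sigma_vap: float = 0.01  # S/m, vaporized tissue
    rho_vap: float = 370.0  # kg/m^3
    c_vap: float = 2156.0  # J/(kg K)
    h_fg: float = 2.25e6  # J/kg, latent heat of vaporization
    rho_blood: float = 1050.0  # kg/m^3
    c_blood: float = 3617.0  # J/(kg K)
    T_blood: float = 37.0  # °C
    T_body: float = 37.0  # °C

    def __post_init__(self) -> None:
        for f_ in ("sigma_vap", "rho_vap", "c_vap", "h_fg", "rho_blood", "c_blood"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")


def _load_default_table() -> dict[str, TissueProperties]:
    text = resources.files("ooablate.data").joinpath("tissue_properties.csv").read_text()
    out: dict[str, TissueProperties] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["name"]] = TissueProperties(
            name=row["name"],
            rho=float(row["density_kg_m3"]),
            sigma0=float(row["electrical_conductivity_S_m"]),
            c=float(row["specific_heat_J_kgK"]),
            k0=float(row["thermal_conductivity_W_mK"]),
            omega=float(row["perfusion_coefficient_per_s"]),
            water_fraction=float(row["water_fraction"]),
        )
    return out


@dataclass
class TissueRegistry:
    """Named tissue table plus the shared model constants.

    The default registry carries exactly the seven materials of the study
    (electrode, plastic, nidus, sclerotic, trabecular, cortical, muscle);
    custom registries (e.g. single synthetic materials for verification
    problems) may hold any set of tissues.
    """

    tissues: dict[str, TissueProperties]
    constants: ModelConstants = field(default_factory=ModelConstants)

    @classmethod
    def default(cls, constants: ModelConstants | None = None) -> "TissueRegistry":
        reg = cls(_load_default_table(), constants or ModelConstants())
        missing = set(DEFAULT_TISSUES) - set(reg.tissues)
        if missing:  # pragma: no cover - packaging error
            raise RuntimeError(f"default tissue table incomplete: {missing}")
        return reg

    def __getitem__(self, name: str) -> TissueProperties:
        try:
            return self.tissues[name]
        except KeyError:
            raise KeyError(
                f"unknown tissue {name!r}; known: {sorted(self.tissues)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.tissues

    def with_overrides(
        self, overrides: Mapping[str, Mapping[str, float]] | None
    ) -> "TissueRegistry":
        """New registry with per-tissue field overrides applied.

        ``overrides`` maps tissue name -> {field name -> value}, e.g.
        ``{"nidus": {"sigma0": 0.5}}``.  Unknown tissues or fields raise.
        """
        if not overrides:
            return self
        tissues = dict(self.tissues)
        for tname, fields_ in overrides.items():
            base = self[tname]
            for fname in fields_:
                if not hasattr(base, fname):
                    raise KeyError(f"tissue {tname!r} has no field {fname!r}")
            tissues[tname] = replace(base, **dict(fields_))
        return TissueRegistry(tissues, self.constants)

    def zero_perfusion(self) -> "TissueRegistry":
        """Registry copy with every perfusion coefficient set to zero
        (ex-vivo conditions)."""
        return TissueRegistry(
            {n: replace(t, omega=0.0) for n, t in self.tissues.items()},
            self.constants,
        )

    # -- scalar/array property models -------------------------------------

    def electrical_conductivity(self, tissue: str, T):
        """sigma(T) in S/m for one tissue; T in °C (scalar or array)."""
        return _sigma_of_T(self[tissue].sigma0, np.asarray(T, float), self.constants)

    def thermal_conductivity(self, tissue: str, T):
        """k(T) in W/(m K); linear rise capped at the 100 °C value."""
        return _k_of_T(self[tissue].k0, np.asarray(T, float), self.constants)

    def enthalpy(self, tissue: str, T):
        """Volumetric enthalpy h(T) in J/m^3, zero at 37 °C."""
        t = self[tissue]
        return _enthalpy(
            t.rho, t.c, t.water_fraction, np.asarray(T, float), self.constants
        )

    def apparent_heat_capacity(self, tissue: str, T):
        """dh/dT in J/(m^3 K) (piecewise slope of the enthalpy)."""
        t = self[tissue]
        return _capacity(
            t.rho, t.c, t.water_fraction, np.asarray(T, float), self.constants
        )

    def perfusion_sink(self, tissue: str, T, alive=True):
        """Pennes perfusion heat loss Qp in W/m^3; exactly 0 when dead."""
        t = self[tissue]
        T = np.asarray(T, float)
        q = t.omega * self.constants.rho_blood * self.constants.c_blood * (
            T - self.constants.T_blood
        )
        return np.where(np.asarray(alive, bool), q, 0.0)

    def arrays_for(self, labels: np.ndarray) -> "TissueArrays":
        """Per-element baseline property arrays for a label array."""
        return TissueArrays.from_labels(self, labels)


# ---------------------------------------------------------------------------
# vectorized kernels (shared by the scalar API and the per-element arrays)


def _sigma_of_T(sigma0, T, mc: ModelConstants):
    s_lin = sigma0 * (1.0 + mc.d_sigma_rel * (T - 37.0))
    s100 = sigma0 * (1.0 + mc.d_sigma_rel * 63.0)
    ramp = s100 + (mc.sigma_vap - s100) * (T - 100.0) / 5.0
    out = np.where(T <= 100.0, s_lin, np.where(T <= 105.0, ramp, mc.sigma_vap))
    return out if out.ndim else float(out)

def _k_of_T(k0, T, mc: ModelConstants):
    Tc = np.minimum(T, 100.0)
    slope = k0 * mc.d_k if mc.d_k_relative else mc.d_k
    out = k0 + slope * (Tc - 37.0)
    return out if np.ndim(out) else float(out)

def _enthalpy(rho, c, Cw, T, mc: ModelConstants):
    sensible = rho * c * (T - 37.0)
    h99 = rho * c * (99.0 - 37.0)
    latent_slope = rho * mc.h_fg * Cw  # J/m^3 per °C over the 1 °C ramp
    h100 = h99 + latent_slope
    mid = h99 + latent_slope * (T - 99.0)
    vap = h100 + mc.rho_vap * mc.c_vap * (T - 100.0)
    phase = np.where(T <= 99.0, sensible, np.where(T <= 100.0, mid, vap))
    # materials with no water never vaporize: pure sensible branch
    out = np.where(np.asarray(Cw) > 0.0, phase, sensible)
    return out if out.ndim else float(out)

def _capacity(rho, c, Cw, T, mc: ModelConstants):
    sens = rho * c * np.ones_like(T)
    latent = rho * mc.h_fg * Cw * np.ones_like(T)
    vap = mc.rho_vap * mc.c_vap * np.ones_like(T)
    phase = np.where(T <= 99.0, sens, np.where(T <= 100.0, latent, vap))
    out = np.where(np.asarray(Cw) > 0.0, phase, sens)
    return out if out.ndim else float(out)


@dataclass
class TissueArrays:
    """Baseline properties broadcast onto mesh elements (one entry each)."""

    rho: np.ndarray
    sigma0: np.ndarray
    c: np.ndarray
    k0: np.ndarray
    omega: np.ndarray
    water_fraction: np.ndarray
    constants: ModelConstants

    @classmethod
    def from_labels(cls, registry: TissueRegistry, labels: np.ndarray) -> "TissueArrays":
        names = sorted(set(labels.tolist()))
        idx = {n: i for i, n in enumerate(names)}
        code = np.array([idx[l] for l in labels.tolist()], dtype=np.intp)
        def col(attr):
            table = np.array([getattr(registry[n], attr) for n in names])
            return table[code]
        return cls(
            rho=col("rho"),
            sigma0=col("sigma0"),
            c=col("c"),
            k0=col("k0"),
            omega=col("omega"),
            water_fraction=col("water_fraction"),
            constants=registry.constants,
        )

    def sigma(self, T: np.ndarray) -> np.ndarray:
        return _sigma_of_T(self.sigma0, T, self.constants)

    def k(self, T: np.ndarray) -> np.ndarray:
        return _k_of_T(self.k0, T, self.constants)

    def enthalpy(self, T: np.ndarray) -> np.ndarray:
        return _enthalpy(self.rho, self.c, self.water_fraction, T, self.constants)

    def capacity(self, T: np.ndarray) -> np.ndarray:
        return _capacity(self.rho, self.c, self.water_fraction, T, self.constants)
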