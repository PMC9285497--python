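"""Axisymmetric scenario geometries for RF ablation of osteoid osteoma.

All geometries live in the (r, z) half-plane (r >= 0, millimetres) with the
origin at the centre of the electrode active tip and the z axis along the
electrode.  Three anatomical scenarios are provided:

``a``
    nidus (1 cm sphere) wrapped in a sclerotic shell, inside trabecular
    bone, bounded laterally by a cortical wall, muscle outside;
``b``
    nidus in trabecular bone close to the cortical wall (thin trabecular
    gap), no sclerosis;
``c``
    intracortical nidus: the tumour sits directly in cortical bone, with
    muscle beyond the cortical box both laterally and above;
``validation``
    ex-vivo bench layout: an agarose-filled nidus cavity in bone separated
    from surrounding soft tissue by a cortical lamella of configurable
    thickness, with temperature probes at 0, 5 and 10 mm from the
    periosteum (outer lamella surface).

The electrode is a gauge-17 shaft (0.7365 mm radius by default) with a
7.5 mm conducting active tip centred on the nidus; the insulated shaft
extends out of the top of the domain.  Region polygons tile the bounding
box exactly (shapely booleans on shared boundary polylines), which the
mesher relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = ["ElectrodeSpec", "RegionGeometry", "build_scenario", "SCENARIO_IDS"]

SCENARIO_IDS = ("a", "b", "c", "validation")

#: max arc segment length (mm) used when discretising circles; fine enough
#: that polygon areas agree with the analytic circle areas to ~1e-5.
_ARC_SEG = 0.12

# parameters accepted by every scenario
_COMMON_DEFAULTS = {
    "domain_radius": 40.0,
    "domain_halfheight": 40.0,
    "electrode_radius": 0.7365,  # 17 G outer radius
    "tip_length": 7.5,
    "nidus_radius": 5.0,
}

_SCENARIO_DEFAULTS = {
    "a": {
        "sclerotic_thickness": 1.0,
        "trabecular_outer_radius": 10.0,
        "cortical_thickness": 4.0,
    },
    "b": {
        "trabecular_gap": 1.0,
        "cortical_thickness": 4.0,
    },
    "c": {
        "cortical_lateral_radius": 30.0,
        "cortical_top": 12.0,
    },
    "validation": {
        "lamella_thickness": 3.0,
    },
}


@dataclass(frozen=True)
class ElectrodeSpec:
    """Electrode geometry (mm): conducting tip centred at the origin.

    The metal region is the active tip only; the rest of the needle (same
    outer radius, extending out of the top of the domain) is modelled as
    the plastic insulator, so the shaft neither carries current nor acts
    as a thermally conducting fin.
    """

    shaft_radius: float = 0.7365
    tip_length: float = 7.5

    @property
    def tip_top(self) -> float:
        return self.tip_length / 2.0

    @property
    def tip_bottom(self) -> float:
        return -self.tip_length / 2.0

    @property
    def outer_radius(self) -> float:
        return self.shaft_radius


@dataclass
class RegionGeometry:
    """Region-tagged planar geometry of one scenario (coordinates in mm)."""

    scenario_id: str
    regions: dict[str, Polygon]
    electrode: ElectrodeSpec
    r_max: float
    z_min: float
    z_max: float
    params: dict[str, float] = field(default_factory=dict)
    probe_points: list[tuple[float, float]] = field(default_factory=list)
    initial_temperature: float = 37.0  # °C (35 for the ex-vivo layout)
    ex_vivo: bool = False  # no blood perfusion when True

    def region_areas(self) -> dict[str, float]:
        """Analytic (finely discretised) region areas in mm^2."""
        return {name: poly.area for name, poly in self.regions.items()}

    def bounding_area(self) -> float:
        return self.r_max * (self.z_max - self.z_min)

    def check(self, tol: float = 1e-4) -> None:
        """Verify the tiling invariants (no gaps/overlaps, r >= 0)."""
        total = sum(self.region_areas().values())
        if abs(total - self.bounding_area()) > tol * self.bounding_area():
            raise ValueError(
                f"regions do not tile the bounding box: {total:.6g} vs "
                f"{self.bounding_area():.6g} mm^2"
            )
        for name, poly in self.regions.items():
            minr = poly.bounds[0]
            if minr < -1e-9:
                raise ValueError(f"region {name!r} extends to r < 0")


def _half_disc(radius: float) -> Polygon:
    """Half-disc of given radius in r >= 0, centred at the origin."""
    n = max(24, int(math.ceil(math.pi * radius / _ARC_SEG)))
    theta = np.linspace(math.pi / 2.0, -math.pi / 2.0, n + 1)
    pts = [(radius * math.cos(t), radius * math.sin(t)) for t in theta]
    pts[0] = (0.0, radius)
    pts[-1] = (0.0, -radius)
    return Polygon(pts)


def _clean(poly) -> Polygon:
    """Drop slivers from boolean ops; keep the largest piece."""
    if poly.is_empty:
        raise ValueError("degenerate (empty) region produced")
    if poly.geom_type == "Polygon":
        return poly
    parts = [g for g in poly.geoms if g.area > 1e-9]
    if len(parts) != 1:
        raise ValueError(f"region is not simply connected ({len(parts)} parts)")
    return parts[0]


def _merge_params(scenario_id: str, overrides: dict | None) -> dict[str, float]:
    params = dict(_COMMON_DEFAULTS)
    params.update(_SCENARIO_DEFAULTS[scenario_id])
    for key, val in (overrides or {}).items():
        if key not in params:
            raise ValueError(
                f"unknown geometry parameter {key!r} for scenario "
                f"{scenario_id!r}; allowed: {sorted(params)}"
            )
        params[key] = float(val)
    for key, val in params.items():
        if val <= 0:
            raise ValueError(f"geometry parameter {key!r} must be positive, got {val}")
    return params


def build_scenario(scenario_id: str, geometry_overrides: dict | None = None) -> RegionGeometry:
    """Build the region-tagged geometry of one scenario.

    Parameters
    ----------
    scenario_id:
        One of ``'a'``, ``'b'``, ``'c'`` or ``'validation'``.
    geometry_overrides:
        Optional mapping of declared parameters (mm) to new values, e.g.
        ``{"nidus_radius": 4.0}``.  Unknown keys or non-positive values are
        rejected with a message naming the offending parameter.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}"
        )
    p = _merge_params(scenario_id, geometry_overrides)

    rmax = p["domain_radius"]
    zmax = p["domain_halfheight"]
    zmin = -zmax
    el = ElectrodeSpec(p["electrode_radius"], p["tip_length"])
    rn = p["nidus_radius"]
    if rn + 1.0 >= rmax:
        raise ValueError("nidus_radius too large for domain_radius")
    if el.tip_top >= rn + 25.0 or el.shaft_radius >= rn:
        raise ValueError("electrode_radius/tip_length incompatible with nidus_radius")

    domain = box(0.0, zmin, rmax, zmax)
    metal = box(0.0, el.tip_bottom, el.shaft_radius, el.tip_top)
    plastic = box(0.0, el.tip_top, el.shaft_radius, zmax)
    probe = metal.union(plastic)

    nidus = _clean(_half_disc(rn).difference(probe))
    regions: dict[str, Polygon] = {"electrode": metal, "plastic": plastic, "nidus": nidus}
    probe_points: list[tuple[float, float]] = []

    if scenario_id == "a":
        rs = rn + p["sclerotic_thickness"]
        rt = p["trabecular_outer_radius"]
        rc = rt + p["cortical_thickness"]
        if not rs < rt < rc < rmax:
            raise ValueError(
                "require nidus_radius + sclerotic_thickness < trabecular_outer_radius"
                " < trabecular_outer_radius + cortical_thickness < domain_radius"
            )
        regions["sclerotic"] = _clean(
            _half_disc(rs).difference(_half_disc(rn)).difference(probe)
        )
        regions["trabecular"] = _clean(
            box(0.0, zmin, rt, zmax).difference(_half_disc(rs)).difference(probe)
        )
        regions["cortical"] = box(rt, zmin, rc, zmax)
        regions["muscle"] = box(rc, zmin, rmax, zmax)
    elif scenario_id == "b":
        rt = rn + p["trabecular_gap"]
        rc = rt + p["cortical_thickness"]
        if not rc < rmax:
            raise ValueError("cortical wall exceeds domain_radius")
        regions["trabecular"] = _clean(
            box(0.0, zmin, rt, zmax).difference(_half_disc(rn)).difference(probe)
        )
        regions["cortical"] = box(rt, zmin, rc, zmax)
        regions["muscle"] = box(rc, zmin, rmax, zmax)
    elif scenario_id == "c":
        # intracortical nidus: the bone is a thick slab whose longitudinal
        # axis lies along +r, with a thin cortical roof above the nidus and
        # soft tissue (muscle) beyond the slab and above it
        rc = p["cortical_lateral_radius"]
        zc = p["cortical_top"]
        if not (rn < rc < rmax and rn < zc < zmax):
            raise ValueError(
                "require nidus_radius < cortical_top < domain_halfheight and "
                "nidus_radius < cortical_lateral_radius < domain_radius"
            )
        cort = box(0.0, zmin, rc, zc).difference(_half_disc(rn)).difference(probe)
        regions["cortical"] = _clean(cort)
        regions["muscle"] = _clean(
            domain.difference(box(0.0, zmin, rc, zc)).difference(probe)
        )
    else:  # validation
        rl = rn + p["lamella_thickness"]
        if not rl < rmax - 11.0:
            raise ValueError("lamella_thickness leaves no room for the 10 mm probe")
        regions["cortical"] = _clean(
            _half_disc(rl).difference(_half_disc(rn)).difference(probe)
        )
        regions["muscle"] = _clean(domain.difference(_half_disc(rl)).difference(probe))
        probe_points = [(rl, 0.0), (rl + 5.0, 0.0), (rl + 10.0, 0.0)]

    geom = RegionGeometry(
        scenario_id=scenario_id,
        regions=regions,
        electrode=el,
        r_max=rmax,
        z_min=zmin,
        z_max=zmax,
        params=p,
        probe_points=probe_points,
        initial_temperature=35.0 if scenario_id == "validation" else 37.0,
        ex_vivo=scenario_id == "validation",
    )
    geom.check()
    return geom


def boundary_network(geom: RegionGeometry):
    """Merged network of all region boundaries (each shared edge once)."""
    return unary_union([poly.boundary for poly in geom.regions.values()])


def tissue_labels(geom: RegionGeometry) -> list[str]:
    return sorted(geom.regions)
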