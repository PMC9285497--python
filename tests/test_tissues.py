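"""Tissue registry and temperature-dependent property models."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ooablate.tissues import DEFAULT_TISSUES, ModelConstants, TissueRegistry

BREAKPOINTS = (99.0, 100.0, 105.0)
EPS = 1e-6


@pytest.fixture(scope="module")
def reg():
    return TissueRegistry.default()


def test_registry_contains_the_seven_materials(reg):
    assert set(reg.tissues) == set(DEFAULT_TISSUES)
    nidus = reg["nidus"]
    assert nidus.sigma0 == 0.22
    assert nidus.rho == 1046
    assert nidus.c == 2726
    assert nidus.water_fraction == 0.60
    assert reg["cortical"].k0 == 0.32
    assert reg["cortical"].omega == 0.0
    assert reg["muscle"].sigma0 == 0.446
    for t in reg.tissues.values():
        assert t.water_fraction <= 1.0
        assert min(t.rho, t.sigma0, t.c, t.k0) > 0


def test_unknown_tissue_raises(reg):
    with pytest.raises(KeyError, match="unknown tissue"):
        reg.electrical_conductivity("bone marrow", 37.0)


@pytest.mark.parametrize(
    "tissue, T, expected",
    [
        ("nidus", 37.0, 0.22),  # baseline at body temperature
        ("muscle", 57.0, 0.446 * 1.30),  # +1.5 %/°C over 20 °C
        ("nidus", 110.0, 0.01),  # fully vaporized
        ("muscle", 110.0, 0.01),
        ("nidus", 102.5, 0.5 * (0.22 * (1 + 0.015 * 63) + 0.01)),  # ramp midpoint
    ],
)
def test_electrical_conductivity_values(reg, tissue, T, expected):
    assert reg.electrical_conductivity(tissue, T) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "tissue, T, expected",
    [
        ("cortical", 37.0, 0.32),
        ("cortical", 100.0, 0.32 + 0.003 * 63),
        ("cortical", 150.0, 0.32 + 0.003 * 63),  # capped above 100 °C
    ],
)
def test_thermal_conductivity_values(reg, tissue, T, expected):
    assert reg.thermal_conductivity(tissue, T) == pytest.approx(expected, rel=1e-12)


def test_thermal_conductivity_relative_reading():
    reg = TissueRegistry.default(ModelConstants(d_k_relative=True))
    # relative reading: 0.3 % of the baseline per °C
    assert reg.thermal_conductivity("cortical", 47.0) == pytest.approx(
        0.32 * (1 + 10 * 0.003), rel=1e-12
    )


def test_enthalpy_values(reg):
    # sensible branch: rho*c*(T - 37)
    assert reg.enthalpy("nidus", 50.0) == pytest.approx(1046 * 2726 * 13, rel=1e-12)
    # latent jump across the 99-100 °C ramp carries rho*h_fg*C per volume
    jump = reg.enthalpy("nidus", 100.0) - reg.enthalpy("nidus", 99.0)
    assert jump == pytest.approx(1046 * 2.25e6 * 0.60, rel=1e-12)
    assert reg.enthalpy("muscle", 37.0) == 0.0
    # materials without water never take the latent branch
    e = reg["electrode"]
    assert reg.enthalpy("electrode", 120.0) == pytest.approx(
        e.rho * e.c * (120 - 37), rel=1e-12
    )


def test_perfusion_sink(reg):
    assert reg.perfusion_sink("cortical", 80.0, alive=True) == 0.0
    assert reg.perfusion_sink("nidus", 47.0, alive=False) == 0.0
    expected = 48e-4 * 1050 * 3617 * 10  # omega * rho_b * c_b * (T - Tb)
    assert reg.perfusion_sink("nidus", 47.0, alive=True) == pytest.approx(expected)


@pytest.mark.parametrize("fn", ["electrical_conductivity", "thermal_conductivity", "enthalpy"])
@pytest.mark.parametrize("tissue", DEFAULT_TISSUES)
@pytest.mark.parametrize("Tb", BREAKPOINTS)
def test_property_continuity_at_branch_points(reg, fn, tissue, Tb):
    """The two-sided difference shrinks with epsilon (no jump, only a
    possibly steep slope such as the electrode's conductivity collapse)."""
    f = getattr(reg, fn)
    gap_wide = abs(f(tissue, Tb + 1e-2) - f(tissue, Tb - 1e-2))
    gap_tight = abs(f(tissue, Tb + EPS) - f(tissue, Tb - EPS))
    scale = max(abs(f(tissue, Tb)), 1e-9)
    assert gap_tight < max(2e-4 * gap_wide, 1e-6 * scale, 1e-12)


@given(T=st.floats(0.0, 140.0))
def test_sigma_shape_and_enthalpy_monotonicity(T):
    reg = TissueRegistry.default()
    # sigma nondecreasing on [0,100], nonincreasing on [100,105]
    s = reg.electrical_conductivity("muscle", T)
    s_up = reg.electrical_conductivity("muscle", min(T + 0.5, 140.0))
    if T + 0.5 <= 100.0:
        assert s_up >= s
    elif 100.0 <= T and T + 0.5 <= 105.0:
        assert s_up <= s
    # enthalpy strictly increasing
    h, h_up = reg.enthalpy("muscle", T), reg.enthalpy("muscle", T + 0.5)
    assert h_up > h
    # apparent capacity at least the sensible value below the vapor branch
    if T <= 100.0:
        assert reg.apparent_heat_capacity("muscle", T) >= 1090 * 3421 - 1e-6


def test_apparent_capacity_is_enthalpy_slope(reg):
    T = np.linspace(38.0, 120.0, 4001)
    h = reg.enthalpy("nidus", T)
    c_mid = reg.apparent_heat_capacity("nidus", 0.5 * (T[:-1] + T[1:]))
    slope = np.diff(h) / np.diff(T)
    # agree away from the breakpoints (where the finite difference straddles)
    interior = np.ones(len(slope), bool)
    for Tb in BREAKPOINTS:
        interior &= ~((T[:-1] < Tb) & (T[1:] > Tb))
    assert np.allclose(slope[interior], c_mid[interior], rtol=1e-8)


def test_overrides_and_errors(reg):
    reg2 = reg.with_overrides({"nidus": {"sigma0": 0.5}})
    assert reg2["nidus"].sigma0 == 0.5
    assert reg["nidus"].sigma0 == 0.22  # original untouched
    with pytest.raises(KeyError):
        reg.with_overrides({"nidus": {"conductivity": 0.5}})
    with pytest.raises(KeyError):
        reg.with_overrides({"gel": {"sigma0": 0.5}})
    assert all(t.omega == 0 for t in reg.zero_perfusion().tissues.values())
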