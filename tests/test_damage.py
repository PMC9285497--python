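"""Arrhenius damage integration and cell-death radius extraction, checked
against arbitrary-precision quadrature oracles."""

import numpy as np
import pytest

from ooablate.damage import (
    OMEGA_DEATH,
    RadiusExtractor,
    arrhenius_rate,
    death_probability,
    integrate_damage,
    update_alive,
)
from ooablate.oracles import arrhenius_quadrature, arrhenius_rate_mp, time_to_threshold


def test_rate_matches_arbitrary_precision_oracle():
    for T_C in (37.0, 50.0, 60.0, 90.0):
        T_K = T_C + 273.15
        assert arrhenius_rate(T_K) == pytest.approx(arrhenius_rate_mp(T_K), rel=1e-12)
    # magnitudes: ~3.1e-2 1/s at 50 °C, negligible (~6e-8) at body temperature
    assert arrhenius_rate(323.15) == pytest.approx(3.1e-2, rel=0.05)
    assert arrhenius_rate(310.15) < 1e-7


def test_rate_monotone_and_rejects_nonphysical_temperature():
    T = np.linspace(280.0, 400.0, 200)
    assert (np.diff(arrhenius_rate(T)) > 0).all()
    with pytest.raises(ValueError):
        arrhenius_rate(-1.0)


def test_death_probability_semantics():
    assert death_probability(0.0) == 0.0
    assert death_probability(OMEGA_DEATH) == pytest.approx(0.98995, abs=2e-5)
    assert round(100.0 * death_probability(4.6)) == 99
    assert death_probability(200.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        death_probability(-0.1)


def test_constant_temperature_reaches_threshold_at_the_closed_form_time():
    t_star = time_to_threshold(50.0, OMEGA_DEATH)  # ~148 s at 50 °C
    assert t_star == pytest.approx(148.0, rel=0.05)
    omega = np.zeros(1)
    dt = 0.25
    n = int(round(t_star / dt))
    for _ in range(n):
        omega = integrate_damage(omega, 50.0, 50.0, dt)
    assert omega[0] == pytest.approx(OMEGA_DEATH, rel=0.005)


def test_body_temperature_never_kills():
    omega = integrate_damage(np.zeros(1), 37.0, 37.0, 900.0)
    assert omega[0] < 1e-3


def test_integration_is_additive_and_monotone():
    rng = np.random.default_rng(0)
    temps = 37.0 + 60.0 * rng.random(41)
    om_once = np.zeros(1)
    for T0, T1 in zip(temps[:-1], temps[1:]):
        prev = om_once.copy()
        om_once = integrate_damage(om_once, T0, T1, 0.5)
        assert om_once[0] >= prev[0]
    om_split = np.zeros(1)
    for T0, T1 in zip(temps[:21], temps[1:21]):
        om_split = integrate_damage(om_split, T0, T1, 0.5)
    for T0, T1 in zip(temps[20:-1], temps[21:]):
        om_split = integrate_damage(om_split, T0, T1, 0.5)
    assert om_split[0] == pytest.approx(om_once[0], rel=1e-12)


def test_stepwise_integration_matches_fine_quadrature_oracle():
    """Trapezoidal-temperature stepping at dt=0.5 agrees with 10x-finer
    arbitrary-precision quadrature to < 0.5 % on a heating/cooling trace."""
    t = np.arange(0.0, 60.5, 0.5)
    T = 37.0 + 25.0 * np.sin(np.pi * t / 60.0)  # up to 62 °C and back
    omega = np.zeros(1)
    for T0, T1 in zip(T[:-1], T[1:]):
        omega = integrate_damage(omega, T0, T1, 0.5)
    reference = arrhenius_quadrature(t, T, dt_fine=0.05)
    assert omega[0] == pytest.approx(reference, rel=0.005)


def test_update_alive_is_one_way():
    tris = np.array([[0, 1, 2], [1, 2, 3]])
    alive = np.ones(2, bool)
    omega = np.array([9.0, 9.0, 0.0, 0.0])
    alive = update_alive(alive, omega, tris)
    assert alive.tolist() == [False, True]
    # damage can only grow, so a dead element stays dead
    alive = update_alive(alive, np.zeros(4), tris)
    assert alive.tolist() == [False, True]


@pytest.fixture(scope="module")
def extractor(mesh_a_medium):
    return RadiusExtractor(mesh_a_medium)


class TestRadiusExtraction:
    def test_linear_ramp_crossing(self, mesh_a_medium, extractor):
        # Omega(d) = 9.2 * max(0, 1 - d/10mm): crosses 4.6 at exactly 5 mm
        d = np.hypot(*(mesh_a_medium.nodes * 1e3).T)
        omega = 9.2 * np.maximum(0.0, 1.0 - d / 10.0)
        r = extractor.radius(omega, "perpendicular")
        assert r == pytest.approx(5.0, abs=0.15)

    def test_zero_field_gives_zero_radius(self, extractor, mesh_a_medium):
        assert extractor.radius(np.zeros(mesh_a_medium.n_nodes), "perpendicular") == 0.0
        assert extractor.radius(np.zeros(mesh_a_medium.n_nodes), "parallel") == 0.0

    def test_pointwise_increase_never_shrinks_the_radius(self, extractor, mesh_a_medium):
        d = np.hypot(*(mesh_a_medium.nodes * 1e3).T)
        omega = 9.2 * np.maximum(0.0, 1.0 - d / 10.0)
        r1 = extractor.radius(omega, "perpendicular")
        r2 = extractor.radius(omega * 1.5 + 0.1, "perpendicular")
        assert r2 >= r1

    def test_unknown_direction_rejected(self, extractor, mesh_a_medium):
        with pytest.raises(ValueError, match="direction"):
            extractor.radius(np.zeros(mesh_a_medium.n_nodes), "diagonal")
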