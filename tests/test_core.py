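"""Unit tests of the pure rate laws against hand-computed oracles."""

import math

import pytest

from osmotip import (
    length_rate_from_volume,
    osmolarity,
    osmotic_pressure_rate,
    solve_turgor,
    standard_lilium,
    tip_expansion_rate,
    tip_tension,
    vant_hoff_pressure,
    wall_thickness_rate,
    wall_viscosity,
    water_influx_rate,
)


@pytest.fixture(scope="module")
def p():
    return standard_lilium()


def test_vant_hoff_reference():
    assert vant_hoff_pressure(0.3, 298.15) == pytest.approx(0.74368,
                                                            rel=1e-4)
    with pytest.raises(ValueError):
        vant_hoff_pressure(-0.1, 298.15)


def test_osmolarity_round_trip():
    # 1e-13 osmol in the standard 500-um tube volume
    V = math.pi * 8.0**2 * 500.0
    c = osmolarity(1e-13, V)
    assert c == pytest.approx(1e-13 * 1e15 / V, rel=1e-12)
    with pytest.raises(ValueError):
        osmolarity(1.0, 0.0)


def test_water_influx_at_operating_point(p):
    # influx at the calibrated discrepancy reproduces the volume demand
    # of 12 um/min growth: pi*r^2*0.2 = 40.21 um^3/s
    x = 0.42735
    influx = water_influx_rate(p.P_os_bar, p.A_mem, x + 0.42735, 0.42735)
    assert influx == pytest.approx(math.pi * 64.0 * 0.2, rel=1e-3)


def test_water_influx_sign_convention(p):
    assert water_influx_rate(p.P_os_bar, p.A_mem, 0.2, 0.5) < 0


def test_length_rate_cylinder_identity():
    assert length_rate_from_volume(math.pi * 64.0 * 0.2, 8.0) == \
        pytest.approx(0.2, rel=1e-12)


def test_osmotic_pressure_rate_zero_at_steady(p):
    # at the calibrated steady state accumulation exactly balances
    # dilution
    V = math.pi * p.r**2 * 500.0
    Pi_i = p.Pi_o + 2 * 0.42735
    dV_dt = math.pi * p.r**2 * 0.2
    rate = osmotic_pressure_rate(p.dm_dt, Pi_i, dV_dt, V, p.temperature)
    assert rate == pytest.approx(0.0, abs=1e-9)


def test_tip_tension_reference():
    # dP*r/2 at the calibrated turgor: 0.42735 * 4 = 1.7094
    assert tip_tension(0.42735, 8.0, 0.0) == pytest.approx(1.7094, rel=1e-4)
    # clamped at zero when gamma exceeds the stretching term
    assert tip_tension(0.1, 8.0, 1.0) == 0.0


def test_wall_viscosity_structure(p):
    # eta = eta_0 + alpha * residence; at the calibrated extrusion the
    # steady viscosity is A_tip*T/(E*L_wall) = 8.6846 MPa.s
    eta = wall_viscosity(p.eta_0, p.alpha, p.dVwall_baseline, p.A_tip, 0.25)
    assert eta == pytest.approx(8.6846, rel=1e-3)
    # no extrusion -> capped viscosity
    assert wall_viscosity(1.0, 5.0, 0.0, p.A_tip, 0.25, cap_factor=100.0) \
        == pytest.approx(100.0)


def test_wall_viscosity_monotone_in_residence(p):
    slow = wall_viscosity(p.eta_0, p.alpha, 1.0, p.A_tip, 0.25)
    fast = wall_viscosity(p.eta_0, p.alpha, 10.0, p.A_tip, 0.25)
    assert slow > fast > p.eta_0


def test_tip_expansion_reference(p):
    # E = A_tip*T/(eta*L_wall); calibrated: 2*pi*r*dL/dt = 10.053
    E = tip_expansion_rate(1.70940, 8.68456, 0.25, p.A_tip)
    assert E == pytest.approx(2 * math.pi * 8.0 * 0.2, rel=1e-3)


def test_wall_thickness_rate_balance(p):
    # extrusion exactly balancing stretch: no thickening
    E = 2 * math.pi * 8.0 * 0.2
    assert wall_thickness_rate(0.25 * E, E, p.A_tip, 0.25) == \
        pytest.approx(0.0, abs=1e-12)
    # no stretch: thickening = extrusion / disc area
    assert wall_thickness_rate(2.513, 0.0, p.A_tip, 0.25) == \
        pytest.approx(2.513 / p.A_tip, rel=1e-9)


class TestSolveTurgor:
    def test_reproduces_calibrated_operating_point(self, p):
        eta_star = 8.684558
        dP = solve_turgor(2 * 0.4273504, eta_star, 0.25, p)
        assert dP == pytest.approx(0.4273504, rel=1e-4)

    def test_matches_bisection(self, p):
        # independent root-find of the same balance
        import scipy.optimize as opt

        for dPi, eta, lw in [(0.8, 5.0, 0.2), (1.5, 20.0, 0.4),
                             (0.05, 1.0, 0.05)]:
            def imbalance(dP):
                influx = p.P_os_bar * p.A_mem * (dPi - dP)
                E = p.A_tip * max(0.0, dP * p.r / 2 - p.gamma) / (eta * lw)
                return influx - (p.r / 2.0) * E

            dP = solve_turgor(dPi, eta, lw, p)
            ref = opt.brentq(imbalance, 0.0, dPi, xtol=1e-12)
            assert dP == pytest.approx(ref, abs=1e-9)

    def test_hypertonic_pins_turgor_at_zero(self, p):
        assert solve_turgor(-0.5, 5.0, 0.25, p) == 0.0

    def test_subyield_returns_water_equilibrium(self):
        p = standard_lilium(gamma=0.5)
        # dPi*r/2 = 0.4 <= gamma: film does not yield
        assert solve_turgor(0.1, 5.0, 0.25, p) == pytest.approx(0.1)
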