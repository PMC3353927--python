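"""Calibration closed-form chain and parameter validation."""

import math

import pytest

from osmotip import ModelParameters, spherical_cap_area, standard_lilium


class TestStandardLilium:
    def test_calibrated_rates(self):
        p = standard_lilium()
        # sensor gain K = dVwall*/x* = (0.25*2*pi*8*0.2)/(0.42735)
        assert p.K == pytest.approx(5.8811, rel=1e-3)
        # extrusion balances stretch of a 0.25-um film at 12 um/min
        assert p.dVwall_baseline == pytest.approx(2.51327, rel=1e-4)
        # solute accumulation sustaining Pi_i = 1.5983 MPa at the
        # growth dilution rate
        assert p.dm_dt == pytest.approx(2.5929e-14, rel=1e-3)
        # hardening: steady viscosity 8.6846 minus eta_0 over the
        # 1.2698-s residence time
        assert p.alpha == pytest.approx(6.0511, rel=1e-3)

    def test_operating_point_identities(self):
        p = standard_lilium()
        dV = math.pi * p.r**2 * 0.2
        x = dV / (p.P_os_bar * p.A_mem)
        assert x == pytest.approx(0.42735, rel=1e-3)
        # turgor fraction one half: dP* = x*
        eta_star = p.eta_0 + p.alpha * p.A_tip * 0.25 / p.dVwall_baseline
        E = p.A_tip * (x * p.r / 2) / (eta_star * 0.25)
        assert E == pytest.approx(2 * math.pi * p.r * 0.2, rel=1e-3)

    def test_membrane_area(self):
        p = standard_lilium()
        assert p.A_mem == pytest.approx(2 * math.pi * 8.0 * 20.0, rel=1e-12)

    def test_pi_o(self):
        assert standard_lilium().Pi_o == pytest.approx(0.74368, rel=1e-4)

    def test_permeability_consistency_check(self):
        p = standard_lilium()
        assert p.check_permeability_consistency(1.32e-3)
        assert not p.check_permeability_consistency(2.0e-3)

    def test_eta0_split_preserves_steady_viscosity(self):
        for eta_0 in (0.5, 1.0, 3.0):
            p = standard_lilium(eta_0=eta_0)
            eta_star = p.eta_0 + p.alpha * p.A_tip * 0.25 / p.dVwall_baseline
            assert eta_star == pytest.approx(8.6846, rel=1e-3)

    def test_eta0_above_steady_viscosity_rejected(self):
        with pytest.raises(ValueError):
            standard_lilium(eta_0=20.0)

    def test_overrides_pass_through(self):
        p = standard_lilium(C_o=0.2, dt=0.1)
        assert p.C_o == 0.2 and p.dt == 0.1


class TestValidation:
    def test_nonpositive_core_fields_rejected(self):
        for field in ("r", "P_os_bar", "L_perm", "C_o", "dt"):
            with pytest.raises(ValueError):
                ModelParameters(**{field: 0.0})

    def test_negative_rates_rejected(self):
        for field in ("alpha", "gamma", "K", "dVwall_baseline"):
            with pytest.raises(ValueError):
                ModelParameters(**{field: -1.0})

    def test_replace_returns_new_validated_copy(self):
        p = standard_lilium()
        q = p.replace(C_o=0.4)
        assert q.C_o == 0.4 and p.C_o == 0.3
        with pytest.raises(ValueError):
            p.replace(r=-1.0)


def test_spherical_cap_area():
    # hemisphere: disc radius = sphere radius -> 2*pi*r^2
    assert spherical_cap_area(8.0, 8.0) == pytest.approx(
        2 * math.pi * 64.0, rel=1e-12)
    # shallow cap is close to the flat disc area
    assert spherical_cap_area(100.0, 2.0) == pytest.approx(
        math.pi * 4.0, rel=1e-3)
    with pytest.raises(ValueError):
        spherical_cap_area(2.0, 8.0)
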