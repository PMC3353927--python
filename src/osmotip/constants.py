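"""Physical constants and unit conventions.

The whole package works in a single unit system chosen so that every
quantity of interest is O(0.01-1000):

=============  ==========================================
length         micrometre (um)
time           second (s)
pressure       megapascal (MPa)
volume         cubic micrometre (um^3)
osmolarity     osmole per litre (Osm)
solute amount  osmole (osmol)
viscosity      MPa.s
=============  ==========================================

The only awkward conversion is between solute content (osmol) held in a
cell volume expressed in um^3 and osmolarity in Osm = osmol/L, which
introduces the factor ``UM3_PER_L``.
"""

import math

#: Gas constant in MPa.L.mol^-1.K^-1 (8.314 J/mol/K = 8.314e-3 MPa.L/mol/K).
R_GAS = 8.314e-3

#: Cubic micrometres per litre.
UM3_PER_L = 1e15

#: Partial molar volume of water, cm^3/mol (used for permeability conversion).
V_WATER = 18.0

#: Micrometres per centimetre.
UM_PER_CM = 1e4

PI = math.pi


def rt(temperature: float) -> float:
    """R*T in MPa.L.mol^-1 (equivalently MPa per Osm)."""
    return R_GAS * temperature


def pos_cm_to_pressure_form(p_os_cm: float, temperature: float) -> float:
    """Convert an osmotic permeability from concentration form (cm/s) to
    pressure form (um.MPa^-1.s^-1).

    The van 't Hoff relation Pi = c*RT links a concentration-difference
    flux law to a pressure-difference one: P_bar = P_cm * V_w / (R*T),
    with V_w the molar volume of water.
    """
    rt_cm3 = rt(temperature) * 1000.0  # MPa.cm^3/mol
    return p_os_cm * V_WATER / rt_cm3 * UM_PER_CM


def pressure_form_to_pos_cm(p_os_bar: float, temperature: float) -> float:
    """Inverse of :func:`pos_cm_to_pressure_form`."""
    rt_cm3 = rt(temperature) * 1000.0
    return p_os_bar / UM_PER_CM * rt_cm3 / V_WATER
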