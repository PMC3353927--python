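"""Model parameters and the calibrated standard *Lilium* set.

The parameter container holds every fixed constant and every externally
controllable input of the tip-growth model: geometry of the tube and of
the apical pectin disc, osmotic permeability of the apical zone, the
external medium, the solute accumulation rate, the rheology of the tip
film (initial viscosity, hardening rate, film tension), the osmosensor
gain, and numerical settings (time step, smoothing half-times, bursting
threshold).

``standard_lilium()`` builds the calibrated baseline set.  Rather than
hard-coding opaque constants, the calibration is carried out in closed
form from the observable steady state it is meant to reproduce: a tube
of radius 8 um growing at 12 um/min with an apical wall film 0.25 um
thick, an apical osmotic zone 20 um long of permeability
1.32e-3 cm/s, and a turgor pressure equal to half the internal-external
osmotic pressure difference.  Those five observables pin the sensor
gain K, the solute accumulation rate dm/dt, and the steady film
viscosity; the split of that viscosity between its initial (unhardened)
part and the calcium-hardening contribution is the one genuinely free
rheological choice and is set by ``eta_0``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from .constants import (
    PI,
    UM3_PER_L,
    pos_cm_to_pressure_form,
    pressure_form_to_pos_cm,
    rt,
)

__all__ = ["ModelParameters", "standard_lilium", "spherical_cap_area"]


def spherical_cap_area(r_curvature: float, r_disc: float) -> float:
    """Area of a spherical cap of disc radius ``r_disc`` on a sphere of
    radius ``r_curvature`` (um^2)."""
    if r_disc > r_curvature:
        raise ValueError("disc radius cannot exceed radius of curvature")
    h = r_curvature - math.sqrt(r_curvature**2 - r_disc**2)
    return 2.0 * PI * r_curvature * h


@dataclass(frozen=True)
class ModelParameters:
    """All fixed constants and controllable inputs, in um / s / MPa / Osm.

    Attributes
    ----------
    r : float
        Tube radius, um.  Also used as the tip radius of curvature.
    r_tip : float
        Radius of the apical pectin disc, um.
    A_tip : float
        Area of the apical disc, um^2 (spherical cap by default).
    P_os_bar : float
        Osmotic permeability in pressure form, um.MPa^-1.s^-1.
    L_perm : float
        Length of the osmotically permeable apical zone, um.
    C_o : float
        External medium osmolarity, Osm.
    C_Ca : float
        External calcium concentration, mM (informational; scenarios act
        on ``alpha`` directly, see :mod:`osmotip.hardening`).
    dm_dt : float
        Solute accumulation rate, osmol/s.
    dVwall_baseline : float
        Pectin extrusion rate used when no sensor drives it, um^3/s.
    eta_0 : float
        Initial (unhardened) viscosity of the extruded pectin, MPa.s.
    alpha : float
        Hardening rate: viscosity gained per second of residence in the
        apical film, MPa.s/s.
    gamma : float
        Film tension opposing stretch, MPa.um.
    K : float
        Osmosensor gain coupling (dPi - dP) to wall extrusion,
        um^3.MPa^-1.s^-1.
    temperature : float
        Absolute temperature, K.
    dt : float
        Integration step, s.
    burst_threshold : float
        Wall thickness below which the tip bursts, um.
    expansion_half_time : float
        Exponential smoothing half-time applied to the tip expansion
        rate, s.  This is the lag of the turgor/expansion loop; it sets
        the threshold at which a soft, thin film makes the loop
        oscillate and burst the tip.
    sensor_half_time : float
        Smoothing half-time of the sensed signal, s; stands for the
        response time of the signalling chain between sensor and
        vesicle delivery.
    perturbation_half_time : float
        Smoothing half-time applied to step changes of parameters, s.
    viscosity_cap_factor : float
        Multiple of ``eta_0`` used as the viscosity when extrusion is
        zero (fully hardened film).
    whole_tube_permeable : bool
        If True the osmotic area tracks the whole tube surface
        2*pi*r*L instead of the fixed apical zone.
    """

    r: float = 8.0
    r_tip: float = 2.0
    A_tip: float = field(default_factory=lambda: spherical_cap_area(8.0, 2.0))
    P_os_bar: float = 0.0936
    L_perm: float = 20.0
    C_o: float = 0.3
    C_Ca: float = 0.1
    dm_dt: float = 2.6e-14
    dVwall_baseline: float = 2.513
    eta_0: float = 1.0
    alpha: float = 6.051
    gamma: float = 0.0
    K: float = 5.88
    temperature: float = 298.15
    dt: float = 0.4
    burst_threshold: float = 2e-4
    expansion_half_time: float = 0.3
    sensor_half_time: float = 1.0
    perturbation_half_time: float = 0.2
    viscosity_cap_factor: float = 1e6
    whole_tube_permeable: bool = False

    def __post_init__(self) -> None:
        for name in ("r", "r_tip", "A_tip", "P_os_bar", "L_perm", "C_o",
                     "dm_dt", "eta_0", "temperature", "dt",
                     "burst_threshold", "expansion_half_time",
                     "sensor_half_time", "perturbation_half_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("alpha", "gamma", "K", "dVwall_baseline", "C_Ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.viscosity_cap_factor < 1:
            raise ValueError("viscosity_cap_factor must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def A_mem(self) -> float:
        """Osmotically active membrane area 2*pi*r*L_perm, um^2."""
        return 2.0 * PI * self.r * self.L_perm

    @property
    def P_os_cm(self) -> float:
        """Concentration-form permeability equivalent, cm/s."""
        return pressure_form_to_pos_cm(self.P_os_bar, self.temperature)

    @property
    def RT(self) -> float:
        """R*T, MPa per Osm."""
        return rt(self.temperature)

    @property
    def Pi_o(self) -> float:
        """External osmotic pressure RT*C_o, MPa."""
        return self.RT * self.C_o

    @property
    def eta_cap(self) -> float:
        """Viscosity used for a film receiving no new material, MPa.s."""
        return self.eta_0 * self.viscosity_cap_factor

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def check_permeability_consistency(self, p_os_cm: float,
                                       tol: float = 0.05) -> bool:
        """True if ``p_os_cm`` (cm/s) and ``P_os_bar`` agree via the
        van 't Hoff conversion to within relative tolerance ``tol``."""
        implied = pos_cm_to_pressure_form(p_os_cm, self.temperature)
        return abs(implied - self.P_os_bar) <= tol * self.P_os_bar


def standard_lilium(
    *,
    growth_rate: float = 0.2,
    wall_thickness: float = 0.25,
    turgor_fraction: float = 0.5,
    eta_0: float = 1.0,
    gamma: float = 0.0,
    p_os_bar: float = 0.0936,
    L_perm: float = 20.0,
    C_o: float = 0.3,
    **overrides,
) -> ModelParameters:
    """Calibrated standard parameter set for a growing *Lilium* tube.

    Parameters with a physical identity (radius, permeability, medium,
    zone length) take their measured values; the unprinted rates (sensor
    gain K, solute accumulation dm/dt, hardening alpha) are solved in
    closed form from the steady state they must reproduce:

    * linear growth rate ``growth_rate`` um/s (default 0.2 = 12 um/min),
    * apical wall thickness ``wall_thickness`` um (default 0.25),
    * turgor equal to ``turgor_fraction`` of the osmotic pressure
      difference (default one half).

    The closed-form chain: the water influx needed for growth fixes the
    water-potential discrepancy x* = dV/dt / (P_os*A_mem); the area
    conservation E* = 2*pi*r*dL/dt and thickness balance
    dV_wall* = L_wall*E* fix the extrusion rate and hence the sensor
    gain K = dV_wall*/x*; the tension/viscosity balance fixes the steady
    film viscosity; the solute balance fixes dm/dt.

    The split of the steady viscosity between its unhardened part
    ``eta_0`` and the hardening contribution is the one free rheological
    choice, and it shapes the regime map.  A small ``eta_0`` (well below
    the steady viscosity of ~8.7 MPa.s) makes the film soft enough for
    calcium removal or hypotonic shock to cross the thin-film bursting
    instability, and it pins the steady turgor: the sensed-discrepancy
    contribution to turgor scales with ``eta_0``, so with a small value
    turgor barely moves when the medium osmolarity steps up or down -
    the observed constancy of turgor.  The default 1.0 MPa.s gives both
    while moderate perturbations (hardening halved, medium diluted to
    0.2 Osm) remain comfortably inside the stable regime.
    """
    r = overrides.pop("r", 8.0)
    r_tip = overrides.pop("r_tip", 2.0)
    A_tip = overrides.pop("A_tip", spherical_cap_area(r, r_tip))
    temperature = overrides.pop("temperature", 298.15)

    A_mem = 2.0 * PI * r * L_perm
    dV_dt = PI * r**2 * growth_rate                  # um^3/s
    x_star = dV_dt / (p_os_bar * A_mem)              # dPi - dP, MPa
    dP_star = x_star * turgor_fraction / (1.0 - turgor_fraction)
    dPi_star = dP_star + x_star

    E_star = 2.0 * PI * r * growth_rate              # um^2/s
    dVwall_star = wall_thickness * E_star            # um^3/s
    K = dVwall_star / x_star

    tension = dP_star * r / 2.0 - gamma              # MPa.um
    if tension <= 0:
        raise ValueError("gamma too large for the requested steady state")
    eta_star = A_tip * tension / (E_star * wall_thickness)
    residence = A_tip * wall_thickness / dVwall_star  # s
    alpha = (eta_star - eta_0) / residence
    if alpha < 0:
        raise ValueError("eta_0 exceeds the steady film viscosity")

    RT = rt(temperature)
    Pi_i_star = RT * C_o + dPi_star
    dm_dt = Pi_i_star * dV_dt / (RT * UM3_PER_L)     # osmol/s

    return ModelParameters(
        r=r,
        r_tip=r_tip,
        A_tip=A_tip,
        P_os_bar=p_os_bar,
        L_perm=L_perm,
        C_o=C_o,
        dm_dt=dm_dt,
        dVwall_baseline=dVwall_star,
        eta_0=eta_0,
        alpha=alpha,
        gamma=gamma,
        K=K,
        temperature=temperature,
        **overrides,
    )
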