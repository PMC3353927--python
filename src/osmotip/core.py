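"""Instantaneous rate laws and the algebraic turgor balance.

These are the pure functions at the heart of the osmotic tip-growth
model, one per physical relation:

* van 't Hoff osmotic pressure of a solution,
* osmotic water influx through the permeable apical zone,
* the cylinder identity linking volume influx to linear growth,
* the solute/dilution balance setting the internal osmotic pressure,
* the Young-Laplace tension stretching the apical pectin film,
* the film viscosity with calcium hardening,
* the viscous thin-film expansion law for the tip area,
* volume conservation of the film (extrusion in, stretched area out),
* the quasi-static turgor solution.

Turgor is not an independent state variable: the cytoplasm is treated
as incompressible, so the hydrostatic pressure difference dP is pinned
by the rearranged influx law dP = dPi - (dV/dt)/(P_os*A_mem), which
holds identically at every step.  In the integrator the volume demand
dV/dt comes from the *smoothed* tip expansion rate, so turgor chases
the expansion law with a short lag; when the film is stiff this
converges to the quasi-static balance solved by :func:`solve_turgor`,
and when the film is soft and thin the lagged loop loses stability -
the thin-film oscillation through which the tip bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import PI, UM3_PER_L, rt
from .params import ModelParameters

__all__ = [
    "ModelState",
    "DerivedForces",
    "vant_hoff_pressure",
    "osmolarity",
    "water_influx_rate",
    "length_rate_from_volume",
    "osmotic_pressure_rate",
    "tip_tension",
    "wall_viscosity",
    "tip_expansion_rate",
    "wall_thickness_rate",
    "solve_turgor",
]


@dataclass
class ModelState:
    """Dynamic variables of the growing tube at one instant.

    Attributes
    ----------
    t : float
        Time, s.
    L : float
        Tube length, um.
    m : float
        Osmolyte content, osmol.
    L_wall : float
        Apical wall-film thickness, um.
    E_smooth : float
        Smoothed tip-area expansion throughput, um^2/s.  This is the
        volume demand the water influx balances, so it also determines
        turgor via the rearranged influx law.
    sensor_smooth : float
        Smoothed sensed signal (MPa) as delivered by the signalling
        chain; the active sensor's commanded rate is its gain times
        this value.
    burst : bool
        True once the wall has thinned through the bursting threshold.
    """

    t: float
    L: float
    m: float
    L_wall: float
    E_smooth: float = 0.0
    sensor_smooth: float = 0.0
    burst: bool = False

    def volume(self, params: ModelParameters) -> float:
        """Cell volume pi*r^2*L, um^3."""
        return PI * params.r**2 * self.L

    def pi_internal(self, params: ModelParameters) -> float:
        """Internal osmotic pressure RT*m/V, MPa."""
        return params.RT * osmolarity(self.m, self.volume(params))


@dataclass(frozen=True)
class DerivedForces:
    """Algebraic quantities evaluated from a state (one integrator step)."""

    Pi_i: float       # internal osmotic pressure, MPa
    Pi_o: float       # external osmotic pressure, MPa
    dPi: float        # Pi_i - Pi_o, MPa
    dP: float         # turgor pressure difference, MPa
    T: float          # film tension, MPa.um
    eta: float        # film viscosity, MPa.s
    dV_dt: float      # water influx, um^3/s
    dL_dt: float      # linear growth rate, um/s
    E: float          # tip-area expansion throughput, um^2/s
    dVwall_dt: float  # pectin extrusion rate, um^3/s
    dLwall_dt: float  # wall thickening rate, um/s


def vant_hoff_pressure(c: float, temperature: float) -> float:
    """Osmotic pressure RT*c of a solution of osmolarity ``c`` (MPa).

    Parameters
    ----------
    c : float
        Osmolarity, Osm.  Must be non-negative.
    temperature : float
        Absolute temperature, K.
    """
    if c < 0:
        raise ValueError("osmolarity must be non-negative")
    return rt(temperature) * c


def osmolarity(m: float, volume_um3: float) -> float:
    """Osmolarity (Osm) of ``m`` osmol dissolved in ``volume_um3`` um^3."""
    if volume_um3 <= 0:
        raise ValueError("volume must be strictly positive")
    return m * UM3_PER_L / volume_um3


def water_influx_rate(P_os_bar: float, A_mem: float,
                      dPi: float, dP: float) -> float:
    """Osmotic water influx P_os*A_mem*(dPi - dP), um^3/s.

    Negative values mean efflux (plasmolysis regime).
    """
    if P_os_bar <= 0 or A_mem <= 0:
        raise ValueError("P_os_bar and A_mem must be strictly positive")
    return P_os_bar * A_mem * (dPi - dP)


def length_rate_from_volume(dV_dt: float, r: float) -> float:
    """Linear growth rate of a cylinder: dL/dt = (dV/dt)/(pi*r^2), um/s."""
    if r <= 0:
        raise ValueError("radius must be strictly positive")
    return dV_dt / (PI * r**2)


def osmotic_pressure_rate(dm_dt: float, Pi_i: float, dV_dt: float,
                          V: float, temperature: float) -> float:
    """Rate of change of the internal osmotic pressure, MPa/s.

    From d(Pi_i)/dt with Pi_i = RT*m/V: accumulation RT*dm/dt minus
    dilution Pi_i*dV/dt, divided by the volume.
    """
    if V <= 0:
        raise ValueError("volume must be strictly positive")
    return (rt(temperature) * dm_dt * UM3_PER_L - Pi_i * dV_dt) / V


def tip_tension(dP: float, r: float, gamma: float) -> float:
    """Net stretching tension of the tip film, MPa.um.

    Young-Laplace stretching term dP*r/2 minus the film tension gamma,
    clamped at zero: the film is stretched by pressure but cannot be
    actively contracted.
    """
    if r <= 0:
        raise ValueError("radius must be strictly positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return max(0.0, dP * r / 2.0 - gamma)


def wall_viscosity(eta_0: float, alpha: float, dVwall_dt: float,
                   A_tip: float, L_wall: float,
                   cap_factor: float = 1e6) -> float:
    """Viscosity of the apical film: initial plus hardening term, MPa.s.

    The hardening contribution is ``alpha`` times the mean residence
    time of material in the film, A_tip*L_wall/(dV_wall/dt): slower
    extrusion leaves pectin exposed to calcium cross-linking for
    longer.  With zero extrusion the film is fully hardened and the
    viscosity saturates at ``cap_factor * eta_0``.
    """
    if eta_0 <= 0:
        raise ValueError("eta_0 must be strictly positive")
    if min(alpha, dVwall_dt, A_tip, L_wall) < 0:
        raise ValueError("alpha, dVwall_dt, A_tip, L_wall must be >= 0")
    cap = eta_0 * cap_factor
    if dVwall_dt <= 0.0:
        return cap
    eta = eta_0 + alpha * (A_tip * L_wall) / dVwall_dt
    return min(eta, cap)


def tip_expansion_rate(T: float, eta: float, L_wall: float,
                       A_tip: float) -> float:
    """Area throughput of the stretching tip film, um^2/s.

    The strain rate of a viscous film under tension T is T/(eta*L_wall);
    multiplied by the disc area it gives the rate at which new wall
    area is exported from the apical disc to the shank.  The disc area
    itself stays constant; E is the area flux through it.
    """
    if eta <= 0 or L_wall <= 0 or A_tip <= 0:
        raise ValueError("eta, L_wall and A_tip must be strictly positive")
    return A_tip * T / (eta * L_wall)


def wall_thickness_rate(dVwall_dt: float, E: float, A_tip: float,
                        L_wall: float) -> float:
    """Thickening rate of the apical film by volume conservation, um/s.

    Pectin volume extruded in minus film volume carried out with the
    stretched area, spread over the disc area.
    """
    if A_tip <= 0:
        raise ValueError("A_tip must be strictly positive")
    return (dVwall_dt - L_wall * E) / A_tip


def solve_turgor(dPi: float, eta: float, L_wall: float,
                 params: ModelParameters,
                 A_mem: float | None = None) -> float:
    """Quasi-static turgor pressure difference dP, MPa.

    Solves the incompressibility balance: water influx
    ``P_os*A_mem*(dPi - dP)`` equals the volume opened by tip expansion
    ``(r/2) * A_tip * max(0, dP*r/2 - gamma)/(eta*L_wall)``.  This is
    the fixed point the integrator's lagged turgor loop relaxes to
    whenever that loop is stable; it is used for steady-state analysis
    and as a test oracle.

    With the tension clamp inactive the balance is linear and has a
    unique root between 2*gamma/r and dPi.  If dPi is too small to
    stretch the film at all (dPi*r/2 <= gamma) the film does not yield
    and water equilibrium dP = dPi is the solution.  A negative dPi
    (hypertonic medium) has no non-negative-turgor solution: the
    membrane is at incipient plasmolysis, turgor is pinned at zero and
    water flows out.
    """
    if eta <= 0 or L_wall <= 0:
        raise ValueError("eta and L_wall must be strictly positive")
    if A_mem is None:
        A_mem = params.A_mem
    G = params.P_os_bar * A_mem                      # hydraulic conductance
    C = params.r * params.A_tip / (2.0 * eta * L_wall)
    if dPi < 0.0:
        return 0.0
    if dPi * params.r / 2.0 <= params.gamma:
        return dPi
    return (G * dPi + C * params.gamma) / (G + C * params.r / 2.0)
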