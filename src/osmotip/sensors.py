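"""Osmosensor couplings and the sensor stability screen.

The model needs one of its rate parameters to be under feedback
control: a sensor reads an intensive variable and sets a rate.  Three
readable inputs (the water-potential difference dPi - dP, the osmotic
pressure difference dPi, the turgor dP) and three controllable outputs
(pectin extrusion dV_wall/dt, solute accumulation dm/dt, hardening
alpha) give nine couplings, plus the no-sensor control in which every
rate is a fixed constant.

The standard sensor couples (dPi - dP) to wall extrusion,
dV_wall/dt = K * (dPi - dP), clamped at zero so deposition is only
commanded while water is actually entering.  The sensors are membrane
proteins distributed over the osmotically active zone, so the
aggregate gain of any membrane-delivered output (wall extrusion,
solute accumulation) scales with the zone area A_mem relative to its
calibration value; the hardening rate, a property of the wall
chemistry, does not.  The screen in
:func:`sensor_screen` runs each coupling to (attempted) steady state,
perturbs the external osmolarity, the hardening rate or the osmotic
zone length, and classifies which of growth rate, wall thickness and
turgor shift - the qualitative matrix that singles out the
water-potential/extrusion coupling as the only one stabilising both
turgor and thickness.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

from .constants import PI, UM3_PER_L
from .params import ModelParameters

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .integrator import SteadyStateSummary, TimeCourse

__all__ = [
    "SensorInput",
    "SensorOutput",
    "SensorSpec",
    "NO_SENSOR",
    "standard_sensor",
    "sensor_signal",
    "sensor_command",
    "baseline_targets",
    "enumerate_couplings",
    "OutcomeFlags",
    "classify_outcome",
    "sensor_screen",
]


class SensorInput(str, Enum):
    WATER_POTENTIAL = "water_potential"   # dPi - dP
    OSMOTIC = "osmotic"                   # dPi
    TURGOR = "turgor"                     # dP
    NONE = "none"


class SensorOutput(str, Enum):
    WALL_EXTRUSION = "wall_extrusion"     # dV_wall/dt
    SOLUTE_RATE = "solute_rate"           # dm/dt
    HARDENING = "hardening"               # alpha


@dataclass(frozen=True)
class SensorSpec:
    """One sensed-input / controlled-output coupling.

    ``gain`` has whatever units make output = gain * input work out
    (e.g. um^3.MPa^-1.s^-1 for extrusion control).  ``half_time`` is
    the smoothing half-time of the signalling chain, s.  With
    ``clamp`` set, negative sensed signals command a zero rate.
    """

    input: SensorInput = SensorInput.WATER_POTENTIAL
    output: SensorOutput = SensorOutput.WALL_EXTRUSION
    gain: float = 0.0
    half_time: float = 5.0
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.half_time <= 0:
            raise ValueError("half_time must be strictly positive")

    @property
    def active(self) -> bool:
        return self.input is not SensorInput.NONE

    def label(self) -> str:
        if not self.active:
            return "none"
        sym = {
            SensorInput.WATER_POTENTIAL: "dPi-dP",
            SensorInput.OSMOTIC: "dPi",
            SensorInput.TURGOR: "dP",
        }[self.input]
        out = {
            SensorOutput.WALL_EXTRUSION: "dVwall/dt",
            SensorOutput.SOLUTE_RATE: "dm/dt",
            SensorOutput.HARDENING: "alpha",
        }[self.output]
        return f"{sym}->{out}"


#: The no-sensor control: every rate stays at its fixed baseline value.
NO_SENSOR = SensorSpec(input=SensorInput.NONE, gain=0.0)


def sensor_signal(spec: SensorSpec, dPi: float, dP: float) -> float:
    """The intensive variable the sensor reads, MPa."""
    if spec.input is SensorInput.WATER_POTENTIAL:
        return dPi - dP
    if spec.input is SensorInput.OSMOTIC:
        return dPi
    if spec.input is SensorInput.TURGOR:
        return dP
    raise ValueError("no signal for an inactive sensor")


def sensor_command(spec: SensorSpec, signal: float,
                   area_scale: float = 1.0) -> float:
    """Rate commanded by the sensor for a (smoothed) ``signal``.

    gain * signal, clamped at zero if configured.  For the
    membrane-delivered outputs (wall extrusion, solute accumulation)
    the aggregate gain scales with the osmotic-zone area relative to
    calibration (``area_scale``); the hardening output does not.
    """
    if not spec.active:
        raise ValueError("an inactive sensor commands nothing")
    s = max(0.0, signal) if spec.clamp else signal
    scale = 1.0 if spec.output is SensorOutput.HARDENING else area_scale
    return spec.gain * scale * s


def baseline_targets(params: ModelParameters) -> dict:
    """Closed-form baseline steady state used to calibrate sensor gains.

    Derived from the parameter set alone: the thickness balance of the
    standard coupling pins x* = dPi - dP via the extrusion baseline,
    and the solute balance pins dPi*.  Returns signal and output values
    at that operating point.
    """
    if params.K <= 0:
        raise ValueError("parameter set has no sensor gain to invert")
    A_mem = 2.0 * PI * params.r * params.L_perm
    G = params.P_os_bar * A_mem
    dVwall = params.dVwall_baseline
    x_star = dVwall / params.K
    dV_dt = G * x_star
    Pi_i = params.RT * params.dm_dt * UM3_PER_L / dV_dt
    dPi = Pi_i - params.Pi_o
    dP = dPi - x_star
    return {
        "x": x_star,
        "dPi": dPi,
        "dP": dP,
        "dVwall_dt": dVwall,
        "dm_dt": params.dm_dt,
        "alpha": params.alpha,
    }


def enumerate_couplings(params: ModelParameters) -> list[SensorSpec]:
    """The nine input/output couplings plus the no-sensor control.

    Each gain is auto-calibrated so that the baseline steady state of
    the standard parameter set is a fixed point of that coupling too:
    gain = baseline output / baseline signal.  Whether the coupling can
    actually reach (or hold) that fixed point is what the screen tests.
    """
    base = baseline_targets(params)
    signals = {
        SensorInput.WATER_POTENTIAL: base["x"],
        SensorInput.OSMOTIC: base["dPi"],
        SensorInput.TURGOR: base["dP"],
    }
    outputs = {
        SensorOutput.WALL_EXTRUSION: base["dVwall_dt"],
        SensorOutput.SOLUTE_RATE: base["dm_dt"],
        SensorOutput.HARDENING: base["alpha"],
    }
    specs = []
    for inp, sig in signals.items():
        for out, val in outputs.items():
            specs.append(SensorSpec(input=inp, output=out,
                                    gain=val / sig,
                                    half_time=params.sensor_half_time))
    specs.append(NO_SENSOR)
    return specs


@dataclass(frozen=True)
class OutcomeFlags:
    """Qualitative classification of one perturbation run."""

    growth_changed: bool
    thickness_changed: bool
    turgor_changed: bool
    outcome: str

    def row(self) -> dict:
        return {
            "growth_changed": self.growth_changed,
            "thickness_changed": self.thickness_changed,
            "turgor_changed": self.turgor_changed,
            "outcome": self.outcome,
        }


def classify_outcome(tc: "TimeCourse", pre: "SteadyStateSummary",
                     threshold: float = 0.10,
                     onset: float | None = None) -> OutcomeFlags:
    """Compare the post-perturbation state of ``tc`` to the
    pre-perturbation summary ``pre``.

    A variable counts as changed when its post-perturbation value
    departs from the pre value by more than ``threshold`` relative.
    Three regimes are read differently:

    * a settled run is judged by its trailing-window means;
    * a run that bursts is a wall collapse: growth and thickness have
      changed by definition, while turgor is judged by its mean from
      the perturbation onset until the wall has thinned to half its
      pre-perturbation value - the endgame of a collapse produces
      unbounded pressure swings, but a wall that is driven into
      bursting at an unshifted mean turgor is a turgor that never
      moved;
    * a run that neither settles nor bursts (e.g. growth arrest with
      the osmotic pressure still climbing) counts every variable as
      changed.
    """
    import numpy as np

    if pre is None or not pre.steady:
        raise ValueError("no pre-perturbation steady state to compare against")
    if tc.outcome == "burst":
        t = tc.data["t_s"]
        dp = tc.data["dP_MPa"]
        lw = tc.data["L_wall_um"]
        lo = onset if onset is not None else 0.0
        thin = (lw < 0.5 * pre.L_wall) & (t >= lo)
        hi = float(t[thin][0]) if thin.any() else tc.burst_time
        mask = (t >= lo) & (t < hi)
        if mask.sum() >= 3:
            shift = abs(float(np.mean(dp[mask])) - pre.dP)
            turgor = shift / max(abs(pre.dP), 1e-12) > threshold
        else:
            turgor = True
        return OutcomeFlags(True, True, turgor, "burst")
    post = tc.trailing_summary()
    if not post.steady and post.max_drift > 0.01:
        return OutcomeFlags(True, True, True, tc.outcome)

    def changed(post_val: float, pre_val: float) -> bool:
        scale = max(abs(pre_val), 1e-12)
        return abs(post_val - pre_val) / scale > threshold

    return OutcomeFlags(
        growth_changed=changed(post.dL_dt, pre.dL_dt),
        thickness_changed=changed(post.L_wall, pre.L_wall),
        turgor_changed=changed(post.dP, pre.dP),
        outcome=tc.outcome,
    )


def sensor_screen(params: ModelParameters,
                  specs: list[SensorSpec] | None = None,
                  perturbations: dict | None = None,
                  settle: float = 4000.0,
                  post: float = 3000.0,
                  threshold: float = 0.10) -> "pandas.DataFrame":
    """Run the full coupling x perturbation battery.

    Each active coupling must first *establish* growth: it is run for
    ``settle`` seconds from an isotonic stationary tube (no solute
    load), so the coupling itself has to bootstrap solute accumulation,
    water entry and wall deposition into a growing steady state.
    Couplings that burst, arrest or keep drifting are marked
    ``no_steady_growth`` - these are the couplings that cannot be made
    to grow at all.  The no-sensor control, whose rates are constants
    fixed at the calibrated operating point, cannot bootstrap by
    construction and is instead started at that operating point.

    The survivors are then rerun with each perturbation stepping in at
    ``t = settle`` and classified with :func:`classify_outcome`.  The
    default battery steps the external medium from 0.3 to 0.2 Osm,
    the hardening rate up 50%, and halves the osmotic zone length.
    Returns a tidy DataFrame mirroring the published comparison table.
    """
    import pandas as pd

    from .integrator import run
    from .scenarios import Perturbation, Scenario

    if specs is None:
        specs = enumerate_couplings(params)
    onset = settle
    if perturbations is None:
        perturbations = {
            "Pi_o": Scenario([Perturbation("C_o", "step", onset,
                                           value=params.C_o * 2.0 / 3.0)]),
            "alpha": Scenario([Perturbation("alpha", "step", onset,
                                            value=params.alpha * 1.5)]),
            "L_perm": Scenario([Perturbation("L_perm", "step", onset,
                                             value=params.L_perm * 0.5)]),
        }

    rows = []
    for spec in specs:
        loading = "isotonic" if spec.active else "steady"
        base_tc = run(params, sensor=spec, duration=settle, loading=loading)
        base_summary = base_tc.trailing_summary(tol=0.01)
        min_growth = 0.05 * 0.2  # um/s; 5% of the calibrated baseline
        admits_steady = (base_tc.burst_time is None
                         and base_summary.steady
                         and base_summary.dL_dt > min_growth)
        if not admits_steady:
            for name in perturbations:
                rows.append({"sensor": spec.label(), "perturbation": name,
                             "admits_steady_growth": False,
                             "growth_changed": None,
                             "thickness_changed": None,
                             "turgor_changed": None,
                             "outcome": "no_steady_growth"})
            continue
        for name, scenario in perturbations.items():
            tc = run(params, scenario=scenario, sensor=spec,
                     duration=settle + post, loading=loading)
            flags = classify_outcome(tc, base_summary, threshold=threshold,
                                     onset=onset)
            rows.append({"sensor": spec.label(), "perturbation": name,
                         "admits_steady_growth": True, **flags.row()})
    return pd.DataFrame(rows)


def standard_sensor(params: ModelParameters) -> SensorSpec:
    """The water-potential -> wall-extrusion sensor at the calibrated
    gain of the given parameter set."""
    return SensorSpec(
        input=SensorInput.WATER_POTENTIAL,
        output=SensorOutput.WALL_EXTRUSION,
        gain=params.K,
        half_time=params.sensor_half_time,
    )
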