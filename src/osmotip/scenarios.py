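"""Declarative perturbation schedules and the figure presets.

A :class:`Scenario` is a list of perturbations applied to named model
parameters.  Two shapes exist: a smoothed step to a new value, and a
sinusoid about the baseline value.  ``effective_params`` evaluates the
schedule at a given time, returning a parameter set the integrator can
use directly; step transitions are passed through the exponential
smoothing the integrator also uses for rates, so that an 'abrupt'
perturbation does not inject a discontinuity at the step time.

The module also ships the named presets reproducing the published
simulation conditions: hardening (calcium) steps, medium dilution and
hypertonic steps, whole-tube permeability, and the sinusoidal drives of
the pectin supply, hardening rate and osmotic zone length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import ModelParameters

__all__ = [
    "Perturbation",
    "Scenario",
    "effective_params",
    "PRESETS",
    "get_preset",
    "preset_names",
]

#: Parameters a scenario may drive.
DRIVABLE = ("C_o", "C_Ca", "alpha", "L_perm", "dVwall_baseline",
            "P_os_bar", "dm_dt")


@dataclass(frozen=True)
class Perturbation:
    """One scheduled modification of a model parameter.

    ``shape`` is ``"step"`` (to ``value``, smoothed with the
    perturbation half-time) or ``"sinusoid"`` (baseline times
    ``1 + amplitude*sin(2*pi*frequency*(t-onset)/60 + phase)``).
    ``frequency`` is in cycles per minute, matching how tip-growth
    oscillation rates are reported.
    """

    parameter: str
    shape: str
    onset: float
    value: float | None = None          # step target (absolute)
    amplitude: float = 0.5              # sinusoid, relative
    frequency: float = 1.2              # sinusoid, min^-1
    phase: float = 0.0                  # sinusoid, radians

    def __post_init__(self) -> None:
        if self.parameter not in DRIVABLE:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; "
                f"drivable parameters are {DRIVABLE}")
        if self.shape not in ("step", "sinusoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.shape == "step" and self.value is None:
            raise ValueError("a step perturbation needs a target value")
        if self.shape == "sinusoid" and not 0 <= self.amplitude < 1:
            raise ValueError("sinusoid amplitude must be in [0, 1) "
                             "so the parameter stays positive")

    def evaluate(self, base_value: float, t: float,
                 half_time: float) -> float:
        """Parameter value at time ``t`` given its unperturbed value."""
        if t < self.onset:
            return base_value
        if self.shape == "step":
            # smoothed approach to the new value
            frac = 1.0 - 2.0 ** (-(t - self.onset) / half_time)
            return base_value + (self.value - base_value) * frac
        omega = 2.0 * math.pi * self.frequency / 60.0
        return base_value * (
            1.0 + self.amplitude * math.sin(omega * (t - self.onset)
                                            + self.phase))

    def rate(self, base_value: float, t: float, half_time: float) -> float:
        """Time derivative of the driven value (used for the
        permeable/impermeable zone bookkeeping)."""
        if t < self.onset:
            return 0.0
        if self.shape == "step":
            decay = 2.0 ** (-(t - self.onset) / half_time)
            return (self.value - base_value) * decay * math.log(2.0) / half_time
        omega = 2.0 * math.pi * self.frequency / 60.0
        return base_value * self.amplitude * omega * math.cos(
            omega * (t - self.onset) + self.phase)


@dataclass(frozen=True)
class Scenario:
    """A schedule of perturbations (empty = unperturbed baseline)."""

    perturbations: tuple[Perturbation, ...] = ()
    name: str = ""

    def __init__(self, perturbations=(), name: str = "") -> None:
        object.__setattr__(self, "perturbations", tuple(perturbations))
        object.__setattr__(self, "name", name)


def effective_params(base: ModelParameters, scenario: Scenario | None,
                     t: float) -> ModelParameters:
    """Parameter set in force at time ``t`` under ``scenario``.

    A drive on external calcium ``C_Ca`` is translated into the
    proportional change of the hardening rate ``alpha`` (hardening is
    linear in calcium, see :mod:`osmotip.hardening`).  The osmotic
    membrane area follows ``L_perm`` automatically.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if scenario is None or not scenario.perturbations:
        return base
    changes: dict[str, float] = {}
    for p in scenario.perturbations:
        if p.parameter == "C_Ca":
            new_ca = p.evaluate(base.C_Ca, t, base.perturbation_half_time)
            changes["C_Ca"] = new_ca
            changes["alpha"] = base.alpha * new_ca / base.C_Ca
        else:
            changes[p.parameter] = p.evaluate(
                getattr(base, p.parameter), t, base.perturbation_half_time)
    return base.replace(**changes) if changes else base


def zone_rate(base: ModelParameters, scenario: Scenario | None,
              t: float) -> float:
    """d(L_perm)/dt imposed by the scenario at time ``t`` (um/s)."""
    if scenario is None:
        return 0.0
    total = 0.0
    for p in scenario.perturbations:
        if p.parameter == "L_perm":
            total += p.rate(base.L_perm, t, base.perturbation_half_time)
    return total


# ---------------------------------------------------------------------------
# Figure presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    """A named simulation condition: scenario + parameter tweaks + sensor."""

    name: str
    description: str
    scenario: Scenario = field(default_factory=Scenario)
    param_overrides: dict = field(default_factory=dict)
    sensor: str = "standard"            # "standard" | "none"
    duration: float = 4500.0
    loading: str = "equilibrium"        # initial solute load, see integrator
    L0: float = 500.0                   # initial tube length, um


#: Perturbation onset for sensor-driven presets: growth bootstraps from
#: the stall-loaded stationary state and has settled by then.
_ONSET = 2000.0
#: Onset for fixed-rate (sensorless) presets, which start at the
#: calibrated operating point and settle within seconds.
_ONSET_STEADY = 500.0


def _step(param: str, factor: float | None = None,
          value: float | None = None, onset: float = _ONSET):
    def make(base: ModelParameters) -> Scenario:
        target = value if value is not None else getattr(base, param) * factor
        return Scenario([Perturbation(param, "step", onset, value=target)])
    return make


def _sine(param: str, amplitude: float, frequency: float = 1.2,
          onset: float = _ONSET):
    def make(base: ModelParameters) -> Scenario:
        return Scenario([Perturbation(param, "sinusoid", onset,
                                      amplitude=amplitude,
                                      frequency=frequency)])
    return make


_PRESET_MAKERS: dict[str, dict] = {
    "baseline": dict(
        description="Calibrated standard set, no perturbation",
        scenario=None, duration=2000.0),
    "fig3_alpha_zero": dict(
        description="Hardening removed (alpha -> 0, as when external "
                    "calcium is chelated); the tip thins and bursts",
        scenario=_step("alpha", value=0.0)),
    "fig3_alpha_x20": dict(
        description="Hardening x20 (external calcium 0.1 -> 2 mM); the "
                    "wall thickens and growth arrests",
        scenario=_step("alpha", factor=20.0)),
    "fig3_alpha_half": dict(
        description="Hardening halved; turgor drops, growth rises, "
                    "thickness stays",
        scenario=_step("alpha", factor=0.5)),
    "fig5_dilute": dict(
        description="Medium diluted 0.3 -> 0.2 Osm; faster growth, "
                    "stable turgor and thickness",
        scenario=_step("C_o", value=0.2)),
    "fig5_shock": dict(
        description="Hypotonic shock 0.3 -> 0.01 Osm; bursting",
        scenario=_step("C_o", value=0.01)),
    "fig5_hyper": dict(
        description="Medium raised 0.3 -> 0.4 Osm; slower growth, "
                    "stable turgor and thickness",
        scenario=_step("C_o", value=0.4)),
    "fig6_whole_tube_permeable": dict(
        description="Osmotic area tracks the whole tube surface of a "
                    "short (20 um) tube; growth accelerates with "
                    "length while the sensor keeps the wall thickness",
        scenario=None, param_overrides={"whole_tube_permeable": True},
        duration=200.0, L0=20.0),
    "fig6_whole_tube_permeable_no_sensor": dict(
        description="As fig6_whole_tube_permeable but without the "
                    "sensor; the tip wall thins continually",
        scenario=None, param_overrides={"whole_tube_permeable": True},
        sensor="none", duration=200.0, L0=20.0, loading="steady"),
    "fig10_pectin_sine": dict(
        description="Pectin extrusion driven sinusoidally (+-50%, "
                    "1.2/min) at fixed deposition control (no sensor); "
                    "growth, turgor and thickness all oscillate, then "
                    "the unregulated wall thickens into growth arrest",
        scenario=_sine("dVwall_baseline", 0.5, onset=_ONSET_STEADY),
        sensor="none", loading="steady", duration=1200.0),
    "fig10_alpha_sine": dict(
        description="Hardening rate driven sinusoidally (+-50%, "
                    "1.2/min), no sensor; oscillates, then the "
                    "unregulated wall thickens into growth arrest",
        scenario=_sine("alpha", 0.5, onset=_ONSET_STEADY),
        sensor="none", loading="steady", duration=1200.0),
    "fig11_Lperm_sine": dict(
        description="Osmotic zone length driven sinusoidally (+-1/3, "
                    "1.2/min) with the water-potential sensor: growth "
                    "oscillates ~2x, turgor and thickness stay",
        scenario=_sine("L_perm", 1.0 / 3.0)),
    "fig11_Lperm_sine_no_sensor": dict(
        description="As fig11_Lperm_sine but without the sensor: "
                    "turgor and thickness oscillate visibly during the "
                    "first cycle, then the wall runs away and growth "
                    "arrests",
        scenario=_sine("L_perm", 1.0 / 3.0, onset=_ONSET_STEADY),
        sensor="none", loading="steady", duration=800.0),
}

PRESETS = tuple(sorted(_PRESET_MAKERS))


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str, base: ModelParameters
               ) -> tuple[ModelParameters, Scenario, Preset]:
    """Resolve a named preset against a base parameter set.

    Returns the (possibly overridden) parameters, the scheduled
    scenario, and the preset record (which carries the sensor mode and
    suggested duration).
    """
    try:
        raw = _PRESET_MAKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    params = base.replace(**raw.get("param_overrides", {}))
    maker = raw.get("scenario")
    scenario = maker(params) if maker is not None else Scenario(name=name)
    preset = Preset(
        name=name,
        description=raw["description"],
        scenario=scenario,
        param_overrides=raw.get("param_overrides", {}),
        sensor=raw.get("sensor", "standard"),
        duration=raw.get("duration", 4500.0),
        loading=raw.get("loading", "equilibrium"),
        L0=raw.get("L0", 500.0),
    )
    return params, scenario, preset
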