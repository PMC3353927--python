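"""Run configuration: YAML loading, validation, and resolution.

A run configuration names a parameter set (with optional field
overrides), a scenario (either a named preset or an inline list of
perturbations), the sensor mode, and the numerical/run settings.
``load_config`` parses and validates a YAML file, filling defaults
(standard parameter set, dt = 0.4 s, no perturbation); unknown keys
are reported by name rather than ignored, because a silently dropped
override is the most dangerous kind of configuration bug.

``RunConfig.resolve()`` turns the configuration into the concrete
objects the integrator consumes: a :class:`ModelParameters`, a
:class:`Scenario` and a :class:`SensorSpec` (or sensor mode string).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParameters, standard_lilium
from .scenarios import DRIVABLE, Perturbation, Scenario, get_preset

__all__ = ["RunConfig", "ConfigError", "load_config"]

#: Keys accepted at the top level of a config file.
_TOP_KEYS = {
    "preset", "parameters", "scenario", "sensor", "duration", "dt",
    "record_stride", "loading", "L0", "initial_wall", "seed", "output",
}
_PERTURBATION_KEYS = {
    "parameter", "shape", "onset", "value", "amplitude", "frequency",
    "phase",
}
_PARAM_FIELDS = {f.name for f in ModelParameters.__dataclass_fields__.values()}


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the
    offending field path."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults filled.

    ``preset`` (optional) names a figure preset supplying scenario,
    sensor, loading, duration and initial length; every explicit field
    in the file overrides the preset's suggestion.  ``parameters`` are
    field overrides applied to the standard calibrated set.
    """

    preset: str | None = None
    parameters: dict = field(default_factory=dict)
    perturbations: tuple[Perturbation, ...] = ()
    sensor: str | None = None
    duration: float | None = None
    dt: float | None = None
    record_stride: int = 1
    loading: str | None = None
    L0: float | None = None
    initial_wall: float | None = None
    seed: int | None = None
    output: dict = field(default_factory=dict)

    def resolve(self) -> dict:
        """Concrete run inputs: a dict with ``params``, ``scenario``,
        ``sensor``, ``duration``, ``loading``, ``L0``,
        ``initial_wall`` and ``record_stride`` keys."""
        overrides = dict(self.parameters)
        if self.dt is not None:
            overrides["dt"] = self.dt
        base = standard_lilium(**overrides)
        if self.preset is not None:
            params, scenario, preset = get_preset(self.preset, base)
            sensor = self.sensor or preset.sensor
            duration = self.duration or preset.duration
            loading = self.loading or preset.loading
            L0 = self.L0 if self.L0 is not None else preset.L0
            if self.perturbations:
                scenario = Scenario(self.perturbations, name="inline")
        else:
            params = base
            scenario = Scenario(self.perturbations, name="inline")
            sensor = self.sensor or "standard"
            duration = self.duration or 2000.0
            loading = self.loading or "equilibrium"
            L0 = self.L0 if self.L0 is not None else 500.0
        if duration < params.dt:
            raise ConfigError("duration must be at least one time step")
        return {
            "params": params, "scenario": scenario, "sensor": sensor,
            "duration": duration, "loading": loading, "L0": L0,
            "initial_wall": self.initial_wall,
            "record_stride": self.record_stride,
        }


def _build_perturbation(raw: dict, idx: int) -> Perturbation:
    unknown = set(raw) - _PERTURBATION_KEYS
    if unknown:
        raise ConfigError(
            f"scenario[{idx}]: unknown key(s) {sorted(unknown)}")
    for req in ("parameter", "shape", "onset"):
        if req not in raw:
            raise ConfigError(f"scenario[{idx}]: missing required "
                              f"field {req!r}")
    if raw["parameter"] not in DRIVABLE:
        raise ConfigError(
            f"scenario[{idx}].parameter: {raw['parameter']!r} is not "
            f"drivable; choose from {DRIVABLE}")
    try:
        return Perturbation(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"scenario[{idx}]: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields all defaults.  Unknown keys at any level are
    reported with their field path.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) at top level: {sorted(unknown)}")

    params = raw.get("parameters") or {}
    if not isinstance(params, dict):
        raise ConfigError("parameters: must be a mapping of field "
                          "names to values")
    bad = set(params) - _PARAM_FIELDS
    if bad:
        raise ConfigError(f"parameters: unknown field(s) {sorted(bad)}")

    scen_raw = raw.get("scenario") or []
    if isinstance(scen_raw, dict):
        scen_raw = [scen_raw]
    if not isinstance(scen_raw, list):
        raise ConfigError("scenario: must be a perturbation or a list "
                          "of perturbations")
    perturbations = tuple(_build_perturbation(p, i)
                          for i, p in enumerate(scen_raw))

    sensor = raw.get("sensor")
    if sensor is not None and sensor not in ("standard", "none"):
        raise ConfigError("sensor: must be 'standard' or 'none'")
    loading = raw.get("loading")
    if loading is not None and loading not in ("equilibrium", "isotonic",
                                               "steady"):
        raise ConfigError("loading: must be 'equilibrium', 'isotonic' "
                          "or 'steady'")
    dt = raw.get("dt")
    if dt is not None and dt <= 0:
        raise ConfigError("dt: must be strictly positive")
    stride = raw.get("record_stride", 1)
    if not isinstance(stride, int) or stride < 1:
        raise ConfigError("record_stride: must be a positive integer")
    output = raw.get("output") or {}
    if not isinstance(output, dict):
        raise ConfigError("output: must be a mapping")

    cfg = RunConfig(
        preset=raw.get("preset"),
        parameters=params,
        perturbations=perturbations,
        sensor=sensor,
        duration=raw.get("duration"),
        dt=dt,
        record_stride=stride,
        loading=loading,
        L0=raw.get("L0"),
        initial_wall=raw.get("initial_wall"),
        seed=raw.get("seed"),
        output=output,
    )
    # fail fast on a bad preset name or inconsistent values
    cfg.resolve()
    return cfg
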