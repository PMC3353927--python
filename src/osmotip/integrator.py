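"""Fixed-step time advance of the tip-growth model.

The model equations are advanced by explicit Euler steps of 0.4 s;
convergence is guarded by a step-halving test in the suite rather than
by an adaptive scheme.  Two exponential smoothers run alongside the
state: one on the tip-area expansion rate and one on the sensed signal
(the latency of the signalling chain between sensor and vesicle
delivery).

Turgor closes the loop through the smoothed expansion rate: the water
influx balances the volume demand (r/2)*E_smooth, so the rearranged
influx law gives dP = dPi - (r/2)*E_smooth/(P_os*A_mem) identically,
while E_smooth relaxes towards the viscous expansion law evaluated at
that turgor.  When the film is stiff this lagged loop settles onto the
quasi-static balance; when the film is soft (low hardening) or thin
the loop crosses its stability threshold, expansion and turgor
oscillate at the iteration frequency with growing amplitude, and the
film thickness crashes through the bursting threshold - the model's
thin-film bursting instability.

A run starts from a stationary 500 um tube at water equilibrium with
no expansion in progress, so dP = dPi and no water flows.  Because the
stationary condition fixes only the flux, the initial solute load
dPi(0) is a free choice with three conventions: ``equilibrium``
(default) loads the cell to its stall pressure - the largest osmotic
excess at which the hardened film still does not yield - so growth
begins immediately as solute accumulation raises Pi_i further;
``isotonic`` starts with no osmotic excess at all (Pi_i = Pi_o), the
harshest bootstrap, used by the sensor screen to ask whether a
coupling can start growth from scratch; ``steady`` starts exactly at
the calibrated operating point (solute level, expansion rate and
sensed signal of steady growth), the natural reference for runs whose
deposition rate is a fixed constant rather than sensor-driven, since
those would otherwise thicken their wall without bound while waiting
for growth to start.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .constants import PI, UM3_PER_L
from .params import ModelParameters
from .scenarios import Scenario, effective_params, zone_rate
from .sensors import (
    NO_SENSOR,
    SensorOutput,
    SensorSpec,
    baseline_targets,
    sensor_command,
    sensor_signal,
    standard_sensor,
)

__all__ = [
    "exp_relax",
    "IntegrationError",
    "TimeCourse",
    "SteadyStateSummary",
    "initial_state",
    "stall_pressure",
    "step",
    "run",
    "steady_state_summary",
]

#: Recorded columns, with units, in output order.
COLUMNS = (
    "t_s", "L_um", "Pi_i_MPa", "dPi_MPa", "dP_MPa", "dL_dt_um_s",
    "L_wall_um", "dVwall_dt_um3_s", "eta_MPa_s", "E_um2_s",
    "L_perm_um", "dLperm_dt_um_s", "dLimperm_dt_um_s",
)


class IntegrationError(RuntimeError):
    """Raised when the state leaves the finite domain."""


def exp_relax(current: float, target: float, half_time: float,
              dt: float) -> float:
    """One step of exponential relaxation towards ``target``.

    Returns ``current + (target - current) * (1 - 2**(-dt/half_time))``;
    after one half-time the gap to the target has halved.
    """
    if half_time <= 0 or dt <= 0:
        raise ValueError("half_time and dt must be strictly positive")
    return current + (target - current) * (1.0 - 2.0 ** (-dt / half_time))


@dataclass(frozen=True)
class SteadyStateSummary:
    """Trailing-window means of the key observables."""

    dL_dt: float       # um/s
    dPi: float         # MPa
    dP: float          # MPa
    L_wall: float      # um
    dVwall_dt: float   # um^3/s
    steady: bool
    max_drift: float   # largest relative half-window drift
    window: float      # s


@dataclass
class TimeCourse:
    """Sampled trajectory of a run plus its outcome.

    ``data`` maps column names (with units) to equal-length arrays.
    ``outcome`` is one of ``steady | burst | arrest | unstable |
    running``; ``burst_time`` is set when the tip burst.
    """

    data: dict
    outcome: str
    burst_time: float | None
    params: ModelParameters
    scenario: Scenario | None
    sensor: SensorSpec

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    @property
    def t(self) -> np.ndarray:
        return self.data["t_s"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.data[k] for k in COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def metadata(self) -> dict:
        return {
            "outcome": self.outcome,
            "burst_time_s": self.burst_time,
            "sensor": self.sensor.label(),
            "scenario": [dataclasses.asdict(p)
                         for p in (self.scenario.perturbations
                                   if self.scenario else ())],
            "parameters": dataclasses.asdict(self.params),
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)

    @staticmethod
    def frame_from_csv(path) -> pd.DataFrame:
        return pd.read_csv(path)

    def trailing_summary(self, window: float = 100.0,
                         tol: float = 1e-3) -> SteadyStateSummary:
        """Summary over the trailing ``window`` seconds (never raises;
        a burst trajectory is simply reported as not steady)."""
        return _summarize(self, window, tol)


def _summarize(tc: TimeCourse, window: float, tol: float
               ) -> SteadyStateSummary:
    t = tc.data["t_s"]
    if len(t) < 4:
        raise ValueError("trajectory too short to summarize")
    t_end = t[-1]
    mask = t >= t_end - window
    if mask.sum() < 4:
        raise ValueError("trajectory shorter than the summary window")

    def win(col):
        return tc.data[col][mask]

    means = {c: float(np.mean(win(c))) for c in
             ("dL_dt_um_s", "dPi_MPa", "dP_MPa", "L_wall_um",
              "dVwall_dt_um3_s")}
    # drift: compare the means of the two half-windows
    half = mask.sum() // 2
    max_drift = 0.0
    for c in ("dL_dt_um_s", "dPi_MPa", "dP_MPa", "L_wall_um",
              "dVwall_dt_um3_s"):
        v = win(c)
        m1, m2 = float(np.mean(v[:half])), float(np.mean(v[half:]))
        scale = max(abs(means[c]), 1e-12)
        max_drift = max(max_drift, abs(m2 - m1) / scale)
    steady = (tc.burst_time is None) and max_drift < tol
    return SteadyStateSummary(
        dL_dt=means["dL_dt_um_s"], dPi=means["dPi_MPa"],
        dP=means["dP_MPa"], L_wall=means["L_wall_um"],
        dVwall_dt=means["dVwall_dt_um3_s"],
        steady=steady, max_drift=max_drift, window=window)


def steady_state_summary(tc: TimeCourse, window: float = 100.0,
                         tol: float = 1e-3) -> SteadyStateSummary:
    """Trailing-window steady-state summary of a trajectory.

    Means of growth rate, pressure differences, wall thickness and
    extrusion over the final ``window`` seconds; ``steady`` is set when
    every relative drift between the two half-windows is below ``tol``.
    A burst trajectory has no steady state and raises.
    """
    if tc.burst_time is not None:
        raise ValueError("a burst trajectory has no steady state")
    return _summarize(tc, window, tol)


# ---------------------------------------------------------------------------
# state initialisation and stepping
# ---------------------------------------------------------------------------

def stall_pressure(params: ModelParameters,
                   wall_thickness: float | None = None) -> float:
    """Largest osmotic excess dPi at which the tube stays stationary, MPa.

    With the sensor driving deposition, extrusion vanishes together
    with the water-potential discrepancy, so the film hardens without
    bound as growth slows; self-consistent growth exists only once the
    tension can stretch the film faster than it hardens, which requires
    dPi > 2*gamma/r + 4*alpha*G*L_wall^2 / (K*r^2) with
    G = P_os*A_mem.  Below that threshold the loaded tube sits still.
    """
    L_wall = 0.25 if wall_thickness is None else wall_thickness
    G = params.P_os_bar * params.A_mem
    stall = 2.0 * params.gamma / params.r
    if params.K > 0:
        stall += 4.0 * params.alpha * G * L_wall**2 / (
            params.K * params.r**2)
    return stall


def initial_state(params: ModelParameters, loading: str = "equilibrium",
                  L0: float = 500.0,
                  initial_wall: float | None = None) -> core.ModelState:
    """Stationary tube at water equilibrium.

    No expansion is in progress (E_smooth = 0), so turgor equals the
    osmotic pressure difference and no water flows, whatever the solute
    load.  ``loading`` picks that load: ``"equilibrium"`` (default)
    loads the cell to its :func:`stall_pressure`, the threshold at
    which growth is marginally about to start; ``"isotonic"`` gives it
    no osmotic excess at all, so growth must bootstrap from scratch;
    ``"steady"`` places it exactly at the calibrated operating point,
    including the expansion rate and sensed signal already running.
    """
    if initial_wall is None:
        initial_wall = 0.25
    E0 = x0 = 0.0
    if loading == "steady":
        base = baseline_targets(params)
        dPi0 = base["dPi"]
        x0 = base["x"]
        G = params.P_os_bar * params.A_mem
        E0 = 2.0 * G * x0 / params.r
    elif loading == "equilibrium":
        dPi0 = stall_pressure(params, initial_wall)
    elif loading == "isotonic":
        dPi0 = 0.0
    else:
        raise ValueError(
            "loading must be 'equilibrium', 'isotonic' or 'steady'")
    Pi_i0 = params.Pi_o + dPi0
    V0 = PI * params.r**2 * L0
    m0 = (Pi_i0 / params.RT) * V0 / UM3_PER_L
    return core.ModelState(t=0.0, L=L0, m=m0, L_wall=initial_wall,
                           E_smooth=E0, sensor_smooth=x0)


def _controlled_rates(state: core.ModelState, p: ModelParameters,
                      sensor: SensorSpec, area_scale: float,
                      ) -> tuple[float, float, float]:
    """(dVwall, dm_dt, alpha) in force, given the smoothed signal.

    The baseline solute accumulation rate scales with the
    osmotic-zone area (transporters are a membrane density), as do the
    membrane-delivered outputs of an active sensor; the baseline
    extrusion and hardening rates do not.
    """
    dVwall = p.dVwall_baseline
    dm_dt = p.dm_dt * area_scale
    alpha = p.alpha
    if sensor.active:
        command = sensor_command(sensor, state.sensor_smooth, area_scale)
        if sensor.output is SensorOutput.WALL_EXTRUSION:
            dVwall = command
        elif sensor.output is SensorOutput.SOLUTE_RATE:
            dm_dt = command
        elif sensor.output is SensorOutput.HARDENING:
            alpha = command
    return dVwall, dm_dt, alpha


def step(state: core.ModelState, params: ModelParameters,
         scenario: Scenario | None, sensor: SensorSpec,
         ) -> tuple[core.ModelState, core.DerivedForces]:
    """Advance the model by one Euler step of ``params.dt`` seconds.

    Evaluates the scenario at the current time, sets turgor from the
    smoothed expansion demand via the rearranged influx law, computes
    every instantaneous rate, updates length, solute content and wall
    thickness with those rates, and finally relaxes the two smoothers.
    Returns the new state together with the forces in effect during
    the step (which is what a recorder wants).
    """
    if state.burst:
        raise ValueError("cannot step a burst state")
    t = state.t
    p = effective_params(params, scenario, t)
    A_mem = (2.0 * PI * p.r * state.L if p.whole_tube_permeable
             else p.A_mem)
    area_scale = A_mem / params.A_mem

    V = state.volume(p)
    Pi_i = p.RT * core.osmolarity(state.m, V)
    dPi = Pi_i - p.Pi_o

    # turgor from the volume demand of the smoothed expansion (Eq. 8)
    G = p.P_os_bar * A_mem
    dP = dPi - (p.r / 2.0) * state.E_smooth / G
    dV_dt = core.water_influx_rate(p.P_os_bar, A_mem, dPi, dP)
    dL_dt = core.length_rate_from_volume(dV_dt, p.r)

    dVwall_eff, dm_eff, alpha_eff = _controlled_rates(state, p, sensor,
                                                      area_scale)
    eta = core.wall_viscosity(p.eta_0, alpha_eff, dVwall_eff, p.A_tip,
                              state.L_wall, p.viscosity_cap_factor)
    T = core.tip_tension(dP, p.r, p.gamma)
    E_target = core.tip_expansion_rate(T, eta, state.L_wall, p.A_tip)
    dLwall_dt = core.wall_thickness_rate(dVwall_eff, state.E_smooth,
                                         p.A_tip, state.L_wall)

    # relax the smoothers for the next step
    E_s = exp_relax(state.E_smooth, E_target, p.expansion_half_time, p.dt)
    if sensor.active:
        sig = sensor_signal(sensor, dPi, dP)
        sensor_s = exp_relax(state.sensor_smooth, sig,
                             sensor.half_time, p.dt)
    else:
        sensor_s = state.sensor_smooth

    forces = core.DerivedForces(
        Pi_i=Pi_i, Pi_o=p.Pi_o, dPi=dPi, dP=dP, T=T, eta=eta,
        dV_dt=dV_dt, dL_dt=dL_dt, E=state.E_smooth,
        dVwall_dt=dVwall_eff, dLwall_dt=dLwall_dt)

    new = core.ModelState(
        t=t + p.dt,
        L=state.L + dL_dt * p.dt,
        m=state.m + dm_eff * p.dt,
        L_wall=state.L_wall + dLwall_dt * p.dt,
        E_smooth=E_s,
        sensor_smooth=sensor_s,
    )
    if not all(map(math.isfinite, (new.L, new.m, new.L_wall, new.E_smooth))):
        raise IntegrationError(
            f"non-finite state at t={new.t:.2f}s: "
            f"L={new.L}, m={new.m}, L_wall={new.L_wall}, "
            f"dPi={dPi}, dP={dP}, eta={eta}")
    if new.L_wall <= p.burst_threshold:
        new.burst = True
        new.L_wall = max(new.L_wall, 0.0)
    return new, forces


def run(params: ModelParameters, scenario: Scenario | None = None,
        duration: float = 2000.0, record_stride: int = 1,
        sensor: SensorSpec | str = "standard",
        loading: str = "equilibrium", L0: float = 500.0,
        initial_wall: float | None = None,
        arrest_threshold: float = 0.002,
        window: float = 100.0, tol: float = 1e-3) -> TimeCourse:
    """Integrate the model for ``duration`` seconds and label the outcome.

    ``sensor`` may be a :class:`SensorSpec`, ``"standard"`` (the
    water-potential sensor at the parameter set's gain K) or
    ``"none"`` (all rates at their fixed baselines).  Sampling records
    every ``record_stride``-th step.  Outcomes: ``burst`` once the wall
    thins through the threshold (absorbing; the recorded pressure
    differences drop to zero at the burst sample); ``arrest`` when
    growth has stopped (trailing-window growth rates all below
    ``arrest_threshold`` um/s, whether or not the wall is still
    thickening); ``steady`` for settled growth; otherwise
    ``unstable``.
    """
    if duration <= 0:
        raise ValueError("duration must be strictly positive")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    if isinstance(sensor, str):
        sensor = (standard_sensor(params) if sensor == "standard"
                  else NO_SENSOR if sensor == "none"
                  else None)
        if sensor is None:
            raise ValueError("sensor must be 'standard', 'none' or a "
                             "SensorSpec")

    state = initial_state(params, loading=loading, L0=L0,
                          initial_wall=initial_wall)
    n_steps = int(round(duration / params.dt))
    rec: dict[str, list] = {c: [] for c in COLUMNS}
    burst_time = None

    def record(s: core.ModelState, f: core.DerivedForces | None,
               p_eff: ModelParameters, burst: bool) -> None:
        rec["t_s"].append(s.t)
        rec["L_um"].append(s.L)
        if burst or f is None:
            pi_i = s.pi_internal(p_eff)
            rec["Pi_i_MPa"].append(0.0 if burst else pi_i)
            rec["dPi_MPa"].append(0.0)
            rec["dP_MPa"].append(0.0)
            rec["dL_dt_um_s"].append(0.0)
            rec["dVwall_dt_um3_s"].append(0.0)
            rec["eta_MPa_s"].append(0.0 if burst else p_eff.eta_cap)
            rec["E_um2_s"].append(0.0)
        else:
            rec["Pi_i_MPa"].append(f.Pi_i)
            rec["dPi_MPa"].append(f.dPi)
            rec["dP_MPa"].append(f.dP)
            rec["dL_dt_um_s"].append(f.dL_dt)
            rec["dVwall_dt_um3_s"].append(f.dVwall_dt)
            rec["eta_MPa_s"].append(f.eta)
            rec["E_um2_s"].append(f.E)
        rec["L_wall_um"].append(s.L_wall)
        L_perm_eff = s.L if p_eff.whole_tube_permeable else p_eff.L_perm
        rec["L_perm_um"].append(L_perm_eff)
        dlperm = (0.0 if burst else
                  (rec["dL_dt_um_s"][-1] if p_eff.whole_tube_permeable
                   else zone_rate(params, scenario, s.t)))
        rec["dLperm_dt_um_s"].append(dlperm)
        rec["dLimperm_dt_um_s"].append(rec["dL_dt_um_s"][-1] - dlperm)

    for i in range(n_steps):
        new_state, forces = step(state, params, scenario, sensor)
        if i % record_stride == 0:
            p_eff = effective_params(params, scenario, state.t)
            record(state, forces, p_eff, burst=False)
        state = new_state
        if state.burst:
            burst_time = state.t
            p_eff = effective_params(params, scenario, state.t)
            record(state, None, p_eff, burst=True)
            break

    data = {c: np.asarray(v, dtype=float) for c, v in rec.items()}
    tc = TimeCourse(data=data, outcome="running", burst_time=burst_time,
                    params=params, scenario=scenario, sensor=sensor)
    if burst_time is not None:
        tc.outcome = "burst"
    else:
        summary = tc.trailing_summary(window=window, tol=tol)
        t_arr = data["t_s"]
        trail = data["dL_dt_um_s"][t_arr >= t_arr[-1] - window]
        if np.max(np.abs(trail)) < arrest_threshold:
            tc.outcome = "arrest"
        elif summary.steady:
            tc.outcome = "steady"
        else:
            tc.outcome = "unstable"
    return tc
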