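# Model and numerical methods

## Physical picture

A tip-growing tube of radius `r` is treated as a cylinder of length
`L` filled with an incompressible solution holding `m` osmoles of
solute. Water enters osmotically through a short apical zone of
length `L_perm` (membrane area `A_mem = 2*pi*r*L_perm`); everything
behind that zone is osmotically inert. New wall is laid down at the
apex as a viscous pectin film of thickness `L_wall` covering a small
apical disc of area `A_tip`; turgor stretches the film, exporting wall
area to the rigid shank, and external calcium cross-links the aging
pectin so the film hardens with residence time.

All quantities are kept in one unit system: um, s, MPa, Osm, osmol,
MPa.s. The only conversion constant is um^3 per litre (1e15).

## Rate laws

* Osmotic pressures: `Pi_i = RT*m/V`, `Pi_o = RT*C_o`,
  `dPi = Pi_i - Pi_o` (van 't Hoff).
* Water influx: `dV/dt = P_os * A_mem * (dPi - dP)` with `P_os` the
  osmotic permeability in pressure form (um/MPa/s) and `dP` the
  turgor difference. Cylinder identity: `dL/dt = (dV/dt)/(pi r^2)`.
* Film tension: `T = max(0, dP*r/2 - gamma)` (Young-Laplace stretch
  minus an optional film tension `gamma`).
* Film viscosity: `eta = eta_0 + alpha * residence`, where
  `residence = A_tip*L_wall/(dV_wall/dt)` is the mean age of material
  in the film and `alpha` the calcium hardening rate. With no
  extrusion the film is fully hardened (viscosity capped at a large
  multiple of `eta_0`).
* Tip expansion (area throughput): `E = A_tip*T/(eta*L_wall)`.
* Wall thickness: `d(L_wall)/dt = (dV_wall/dt - L_wall*E)/A_tip`
  (extrusion in, stretched film out).
* Solute: `dm/dt` is a constant pump rate at baseline, or a sensor
  output.
* Osmosensor (standard coupling): pectin extrusion
  `dV_wall/dt = K*(dPi - dP)`, clamped at zero. The sensed signal is
  smoothed with the sensor half-time before it commands the rate.

Turgor is not an independent state: the cytoplasm is incompressible,
so `dP = dPi - (dV/dt)/(P_os*A_mem)` holds identically, with the
volume demand `dV/dt` given by the (smoothed) expansion rate
`(r/2)*E`. When the lagged loop is stable this relaxes to the
quasi-static balance solved in closed form by `solve_turgor`, which
serves as the test oracle.

## Calibration of the standard set

The standard *Lilium* set is derived in closed form from its target
steady state rather than stored as opaque constants: radius 8 um,
permeable zone 20 um, permeability 0.0936 um/MPa/s (= 1.32e-3 cm/s up
to the ~2.5% rounding of those two published figures), medium 0.3 Osm,
growth 12 um/min, apical wall 0.25 um, and turgor equal to half the
internal-external osmotic difference. The chain:

1. influx for 12 um/min fixes the water-potential discrepancy
   `x* = dPi - dP = 0.427 MPa`, hence `dP* = 0.427`, `dPi* = 0.855`;
2. area conservation `E* = 2*pi*r*dL/dt = 10.05 um^2/s` and the
   thickness balance fix the extrusion rate
   `dV_wall* = L_wall*E* = 2.513 um^3/s` and the sensor gain
   `K = dV_wall*/x* = 5.88`;
3. the tension/viscosity balance fixes the steady film viscosity
   `eta* = A_tip*T*/(E* L_wall*) = 8.68 MPa.s`;
4. the solute balance fixes the pump rate `dm/dt = 2.59e-14 osmol/s`.

The split of `eta*` between the unhardened part `eta_0` and the
hardening contribution `alpha * residence` is the one free rheological
choice. The default `eta_0 = 1 MPa.s` is set by the regime map it
must reproduce (see "Role of eta_0" below).

## Time stepping

An explicit scheme with exponential smoothing (step 0.4 s by default):

1. evaluate the effective (possibly perturbed) parameters at `t`;
2. compute `dPi` from the state; turgor from the *smoothed* expansion
   rate: `dP = dPi - (r/2)*E_smooth/(P_os*A_mem)`;
3. evaluate tension, viscosity, expansion target
   `E_target = A_tip*T/(eta*L_wall)`, extrusion (sensor-commanded or
   fixed), solute and thickness rates;
4. advance `L`, `m`, `L_wall` by forward Euler; relax `E_smooth`
   toward `E_target` and the sensed signal toward its current value
   with their half-times;
5. a wall thinner than the bursting threshold (0.2 nm) terminates the
   run: outcome `burst`, recorded pressures zero from the burst
   sample on.

Smoothing makes the loop causal and is also the physics of the burst:
linearising the discrete map of the expansion loop gives a multiplier
`1 - beta*(1 + S/G)` with `beta = 1 - 2^(-dt/half_time)`,
`S = r^2*A_tip/(4*eta*L_wall)` and `G = P_os*A_mem`. The loop
oscillates and diverges when `S/G > 2/beta - 1` (about 2.3 at the
default half-time of 0.3 s): a soft, thin film under a lagged turgor
response is unstable, which is how hypotonic shock and hardening
removal burst the tip. At the calibrated operating point `S/G = 1`,
comfortably stable.

Two properties of the burst collapse are worth noting honestly. The
collapse is violent (a few time steps); its envelope (the running
minimum of the wall thickness) decreases monotonically through the
threshold, but individual samples in the final half-second can
rebound once as the sensed signal surges when the recorded turgor
momentarily goes negative. And the burst-on-hardening-removal regime
depends on the lagged loop: integrated much finer in time, the same
condition settles into a bounded oscillation instead. The acceptance
checks therefore read the collapse at the documented step size.

## Loading conventions

`initial_state` supports three solute loads for a stationary tube of
length `L0`:

* `equilibrium` (default): loaded to the stall pressure
  `dPi_0 = 2*gamma/r + 4*alpha*G*L_wall^2/(K*r^2)` — the largest
  osmotic difference at which the sensor-fed film does not yield, i.e.
  a genuinely stationary, turgid tube. Growth bootstraps from here
  and settles within the 2000-s baseline run.
* `isotonic`: no osmotic difference at all (`Pi_i = Pi_o`). Used by
  the sensor screen: a coupling must build up solute, water entry and
  deposition by itself to establish growth.
* `steady`: the calibrated operating point, including the smoothed
  expansion rate and sensed signal. Used for fixed-rate (sensorless)
  runs, whose constant rates are defined at that operating point; the
  undriven sensorless model holds it with zero drift.

## Area scaling

Sensor-commanded, membrane-delivered outputs (wall extrusion, solute
accumulation) and the baseline pump rate scale with the osmotic-zone
area relative to calibration: the sensors and transporters live on
that membrane. Two things deliberately do not scale: the hardening
rate (wall chemistry, not membrane flux) and the *fixed* sensorless
extrusion rate (in the sensorless control, deposition proceeds at a
constant rate by definition). In whole-tube-permeable mode the zone
is the entire tube surface, so the water influx and the scaled rates
grow with length — growth accelerates with length while the sensor
holds the wall thickness. The explicit thickness map becomes
numerically stiff once `E*dt/A_tip` approaches 2 (tube length of
order 130 um at the default step), so the whole-tube presets run a
short (20 um) tube for 200 s.

## Role of eta_0 and the regime map

Writing the steady turgor of the sensor-controlled model as
`dP = alpha*K/G + (2*K/(r*A_tip)) * eta_0 * g*x` (with `g` the
area scale and `x` the sensed discrepancy) shows that the
perturbation-sensitive part of turgor is proportional to `eta_0`.
A small `eta_0` therefore pins turgor: medium dilution, hypertonic
steps and the sinusoidal zone drive leave `dP` nearly unchanged
(the observed constancy of turgor), while hardening steps move it
through the `alpha*K/G` term. A small `eta_0` also softens the film
enough for hardening removal and hypotonic shock to cross the
oscillatory bursting instability. `eta_0 = 1 MPa.s` achieves both
while the moderate perturbations (hardening halved, dilution to
0.2 Osm) stay inside the stable regime; values below ~1 destabilise
the hardening-halved condition, values well above fail to burst on
hardening removal and let turgor wander.

The flip side, inherent to the model rather than a defect: without
the sensor the wall thickness has no restoring feedback of its own
(the drain `L_wall*E = A_tip*T/eta` is nearly thickness-independent),
so at `eta_0 = 1` the sensorless model is marginally stable. Any
sustained sensorless perturbation runs the wall away — thinning to
burst on the hypotonic side, thickening into growth arrest on the
hardening/hypertonic side — and the sinusoidally driven sensorless
runs oscillate visibly for a cycle and then run away. That contrast
with the sensor-controlled runs is the central point of the model.

## Sensor screen

Three readable inputs (`dPi - dP`, `dPi`, `dP`) times three
controllable outputs (wall extrusion, solute rate, hardening) give
nine couplings plus the no-sensor control; gains are auto-calibrated
so the standard operating point is a fixed point of every coupling.
Each active coupling must first *establish* growth from the isotonic
load within 4000 s; the no-sensor control starts at the operating
point it defines. Survivors are stepped (medium 0.3 to 0.2 Osm,
hardening x1.5, zone length x0.5) and classified on whether growth,
thickness and turgor move by more than 10%. Runs that burst are read
as growth and thickness changed, with turgor judged by its mean from
the onset until the wall has lost half its thickness; runs that
neither settle nor burst (arrest with the osmotic pressure still
climbing) count every variable as changed.

Results with the standard set: every solute-rate coupling and every
turgor-input coupling fails to establish growth (solute couplings
freeze at the isotonic fixed point while deposition piles the wall
up; turgor-input couplings likewise arrest); the osmotic-input
alternatives `dPi -> extrusion` and `dPi -> hardening` also fail to
bootstrap from the isotonic load. The water-potential inputs
establish growth, and only `dPi-dP -> extrusion` stabilises both
turgor and thickness under every perturbation.

## Plasmolysis

Under a hypertonic step the protoplast retracts from the apex; only
the apical zone (length `l`) is permeable, and wall the membrane has
already left is treated as impermeable. The efflux balance
`pi r^2 dx/dt = P_os*dPi*2 pi r (l - x)` integrates to
`x(t) = l*(1 - exp(-k t))` with `k = 2*P_os*dPi/r`: the rate constant
carries the permeability, the plateau carries the zone length, so one
retraction time course identifies both. `fit_retraction` recovers
them by nonlinear least squares and flags a plateau that the record
never approached (span under one `1/k` time) as unidentified.

## Known limitations

* The burst collapse is resolved by a handful of samples at dt=0.4 s;
  its sample-to-sample detail (including one recorded thickness
  rebound and momentarily negative recorded turgor) is a numerical
  artefact of the explicit lagged scheme, while the envelope and the
  outcome are robust.
* The whole-tube-permeable mode is limited to short tubes/times by
  the explicit thickness map's stiffness bound.
* The sensorless model at the default calibration is marginally
  stable in thickness, so sensorless sinusoidal drives show one or
  two clean oscillation cycles before the wall runs away; amplitudes
  of the oscillatory phase, not long-run behaviour, are the
  meaningful output there.
* Smoothing half-times (expansion 0.3 s, sensor 1.0 s, perturbation
  0.2 s) are model choices: substantially shorter half-times
  destabilise the calibrated operating point itself.
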