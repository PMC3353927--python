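# osmotip

A mechanistic simulator of pollen-tube tip growth as an osmotic
machine. The tube is a cylinder fed by osmotic water entry through a
short permeable apical zone; the new wall is laid down at the tip as a
viscous pectin film that is stretched by turgor and hardened by
calcium cross-linking; a water-potential osmosensor feeds back on
pectin deposition. The package also implements the tip-plasmolysis
retraction model used to measure the osmotic permeability and zone
length, and a screen over alternative sensor couplings.

## Quick start

```python
from osmotip import standard_lilium, run

params = standard_lilium()          # calibrated standard parameter set
tc = run(params, duration=2000.0)   # baseline: settles to ~12 um/min
print(tc.outcome)
print(tc.trailing_summary())        # growth, turgor, wall thickness
tc.to_csv("baseline.csv")
```

Perturbations are declarative schedules; the named presets reproduce
the standard simulation conditions (calcium steps, osmotic challenges,
whole-tube permeability, sinusoidal drives):

```python
from osmotip import get_preset, run, standard_lilium

params, scenario, preset = get_preset("fig5_dilute", standard_lilium())
tc = run(params, scenario=scenario, sensor=preset.sensor,
         duration=preset.duration, loading=preset.loading, L0=preset.L0)
```

## Command line

```sh
osmotip presets list                      # available named scenarios
osmotip simulate --preset baseline        # CSV + JSON metadata
osmotip simulate myrun.yml                # YAML run configuration
osmotip screen                            # sensor-coupling matrix
osmotip plasmolysis synth --seed 1 --out curve.csv
osmotip plasmolysis fit curve.csv         # recover P_os and zone length
```

A YAML configuration names a preset and/or overrides parameters:

```yaml
preset: fig11_Lperm_sine
parameters:
  C_o: 0.3
duration: 2500
```

## Layout

- `osmotip.core` — the pure rate laws (osmosis, dilution, film
  stretching, hardening viscosity) and the quasi-static turgor balance.
- `osmotip.params` — the parameter container and the closed-form
  calibration of the standard set.
- `osmotip.integrator` — the explicit lagged-turgor time stepper,
  outcome classification, time-course serialization.
- `osmotip.sensors` — osmosensor couplings and the stability screen.
- `osmotip.scenarios` — perturbation schedules and figure presets.
- `osmotip.hardening` — calcium dependence of the hardening rate.
- `osmotip.plasmolysis` — retraction forward model, fitting, synthesis.
- `osmotip.config`, `osmotip.cli` — YAML configuration and CLI.

See `docs/methods.md` for the model equations, the numerical scheme
and its stability properties, and the calibration chain.

## Tests

```sh
python -m pytest            # unit, property and acceptance tests
python scripts/acceptance.py --seed 0 --out acceptance.json
```
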