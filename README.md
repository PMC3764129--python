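# turtlehab

Habitat and movement modelling for juvenile loggerhead sea turtles in the
North Pacific: Argos track cleaning, a Gaussian temperature-preference
feeding-habitat index, and coupled Lagrangian/Eulerian simulations of
habitat-driven movement.

## The scientific problem

Juvenile North Pacific loggerheads spend years in the open ocean between
Japanese nesting beaches and foraging grounds off Baja California. Their
distribution matters for fisheries bycatch: interactions concentrate where
turtles aggregate, and turtles aggregate where the environment suits them.
Predicting those aggregations requires three linked ingredients:

1. **Cleaned trajectories.** Argos satellite fixes arrive irregularly
   (about 2.6 per day) with kilometre-scale errors and occasional large
   spikes. Before any speed or preference statistic is meaningful, tracks
   must be filtered, smoothed and resampled onto a regular time lattice.
2. **A habitat index.** Observed occupancy peaks near a 30-m-layer
   temperature of 17 °C. A Gaussian preference
   Θ(T) = exp(−(T − T_opt)² / (2 σ_T²)) combined with a normalized prey
   proxy gives an accessible-habitat index H_a ∈ [0, 1]; regions with
   H_a > 0.8 are bycatch-relevant hot spots.
3. **A movement model.** Turtles both drift with currents and swim toward
   better habitat, with speed bounded by a size-dependent maximum
   sustainable speed (MSS, in body lengths per second). An
   advection–diffusion equation for population density — habitat-gradient
   taxis plus habitat-modulated diffusivity — propagates a virtual release
   forward in time; an equivalent stochastic particle model generates
   individual synthetic tracks.

`turtlehab` implements all three, plus a synthetic-data module that
emulates gridded ocean forcing (meridional temperature gradient, seasonal
cycle, eddies, a zonal jet, prey proxy) and Argos-degraded tracks, so the
whole pipeline is testable without any external data.

## Worked example

```python
import numpy as np

from turtlehab.synthetic_data import (ForcingSpec, ArgosNoiseSpec, make_forcing,
                                      simulate_individuals, degrade_to_argos)
from turtlehab.habitat_model import HabitatParams, habitat_index
from turtlehab.movement_model import (SimConfig, simulate_density,
                                      density_track_agreement, v_max)
from turtlehab.track_processing import process_tracks

# 1. One year of synthetic forcing on a 0.5-degree North Pacific subdomain
spec = ForcingSpec(lon_min=170.0, lon_max=189.5, lat_min=20.0, lat_max=39.5,
                   grid_step=0.5, time_start="2005-01-01", time_end="2006-01-07", seed=1)
forcing = make_forcing(spec)

# 2. Feeding-habitat index for a 30-cm juvenile cohort
params = HabitatParams(t_opt=17.0, t_sd=1.5, mss=1.1, scl=30.0)
habitat = habitat_index(forcing["temp30m"], forcing["prey"], params)
print(f"v_max = {v_max(params):.2f} m/s; habitat index in "
      f"[{np.nanmin(habitat.h_a.values):.2f}, {np.nanmax(habitat.h_a.values):.2f}]")

# 3. Simulate 30 turtles, degrade to Argos-like sampling, clean them back up
truth = simulate_individuals(forcing, params, 180.0, 30.0, "2005-01-01",
                             n=30, dt_hours=6.0, duration_days=120.0,
                             mode="active", seed=7)
argos = degrade_to_argos(truth, ArgosNoiseSpec(seed=2))
cleaned = [t for t in process_tracks(argos) if not t.discard]
print(f"{len(cleaned)} tracks kept; first track: {cleaned[0].n_raw} raw fixes -> "
      f"{len(cleaned[0].times)} three-hourly fixes "
      f"({cleaned[0].n_removed_speed} speed-filtered, {cleaned[0].n_removed_spike} spikes)")

# 4. Eulerian virtual release of 2000 individuals and track agreement
density = simulate_density(180.0, 30.0, "2005-01-01", 120.0,
                           (forcing["u"], forcing["v"]), habitat, params,
                           SimConfig(n_release=2000), mode="active")
score = density_track_agreement(density, cleaned)
print(f"population after 120 d = {density.total(-1):.6f}")
print(f"mean density percentile at observed fixes = {score['mean_percentile']:.1f} "
      f"(top-quartile coverage {score['top_q_coverage']:.2f}, n = {score['n_obs']})")
```

Output:

```text
v_max = 0.33 m/s; habitat index in [0.00, 0.72]
30 tracks kept; first track: 312 raw fixes -> 959 three-hourly fixes (9 speed-filtered, 16 spikes)
population after 120 d = 2000.000000
mean density percentile at observed fixes = 98.4 (top-quartile coverage 1.00, n = 28794)
```

The closed-boundary solver conserves the 2000-individual release exactly,
and the independently simulated particle tracks sit at the 98th percentile
of the simulated density field — the Lagrangian and Eulerian formulations
agree.

## Command-line interface

The `turtlehab` console script chains the same stages from the shell:

```sh
turtlehab synth-forcing forcing --seed 1
turtlehab synth-tracks forcing tracks_raw.csv --n 30 --argos --seed 2
turtlehab process-tracks tracks_raw.csv tracks_clean.csv
turtlehab habitat forcing habitat.nc --t-opt 17 --t-sd 1.5
turtlehab simulate forcing density.nc --release-lon 180 --release-lat 30 --date 2005-01-01
turtlehab compare density.nc tracks_clean.csv
```

## Testing and reproduction

```sh
pytest -q                 # full suite (unit + end-to-end property tests)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the two headline quantities and writes
them as JSON:

* `t4` — the Gaussian temperature-preference index evaluated exactly at
  the optimum (T_opt = 17.0 °C, σ_T = 1.5 °C): **1.0**, exact.
* `t5` — total population summed over all cells after a 1-year active-mode
  Eulerian simulation with no-flux boundaries on a 40 × 40 synthetic
  domain, for a 2000-individual point release: **2000** to within 1e-6
  relative (measured ≈ 1e-15).

All randomness derives from `--seed` (it seeds the synthetic forcing
generator); re-running with the same seed reproduces the JSON byte for
byte. See `docs/methods.md` for model formulation, numerical choices and
limitations.
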