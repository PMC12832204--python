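# edna-dispersal

Decay-aware Lagrangian dispersal modelling for marine environmental DNA
(eDNA).

## The problem

When a fish sheds DNA into coastal water, the measured concentration does
not always fall off as a single exponential. Tank experiments and a
growing number of field studies show two other patterns: **biphasic**
decay (a rapid early loss followed by a much slower phase) and **delayed**
decay (a several-fold *rise* over the first ~6 h — as intracellular DNA is
released from decaying cells — before the exponential decline). Which
pattern holds changes how far from its source an eDNA signal remains
detectable, and therefore how monitoring surveys should be designed and
interpreted.

This package implements a complete, testable pipeline for studying that
question:

1. **Decay kinetics** (`decay_models`) — the one- and two-exponential
   concentration models

   C(t) = C₀₀·e^(−k·t)  and  C(t) = C₀₁·e^(−k₁·t) + C₀₂·e^(−k₂·t),

   the temperature law k(T) = 0.0419·e^(0.0776·T) h⁻¹, half-life
   computation, nonlinear least-squares fitting with per-tank
   log-amplitude offsets and AIC/R² comparison, and rule-based
   classification of a series as exponential, biphasic or delayed.
2. **Synthetic inputs** (`synthetic_data`) — hourly gridded surface
   currents with the character of a tidally *dynamic* site (speeds
   0.01–2.4 m s⁻¹, semidiurnal period 12.42 h, spring–neap envelope
   14.8 d) and a *quiet* site (0.01–0.6 m s⁻¹), plus tank-experiment
   concentration series (3 temperatures × 2 tanks × 3 technical
   replicates × 8 sampling times, multiplicative lognormal noise).
3. **Particle tracking** (`lagrangian`) — RK4 advection (3-min step) in
   the gridded flow, random-walk diffusion (K = 1 m² s⁻¹), and four
   per-particle fate scenarios: no decay; exponential (per-step Bernoulli
   survival e^(−k(T)Δt)); biphasic (70% of particles at 0.50 h⁻¹, 30% at
   0.013 h⁻¹); delayed (20% of particles duplicated each hour for 6 h —a
   threefold increase — then exponential decay).
4. **Dispersal metrics** (`dispersal_metrics`) — per (scenario, release
   event, hour): particles alive, centre of mass, mean distance from
   release, dispersion about the centre of mass, convex-hull area, and
   particle density inside the hull, plus densities relative to a
   reference scenario's per-hour median.
5. **Variance decomposition** (`variance_decomposition`) — metrics are
   z-scored within (metric × site) groups and decomposed by a three-way
   Type III ANOVA (scenario × metric × hour, release event as a blocking
   term) with partial η² effect sizes.
6. **Orchestration** (`cli`) — an `edna-dispersal` command with
   subcommands (`synth-flow`, `synth-decay`, `simulate`, `metrics`,
   `decompose`, `fit-decay`, `classify`, `run-all`) and a `run_pipeline`
   function that executes every stage from one YAML config with full
   seeded reproducibility and a JSON manifest.

## Worked example

```python
import pandas as pd
import edna_dispersal as ed

# a tidal flow field around the quiet site, two days, 500-m grid
grid = ed.FieldGridSpec.centered_on(
    ed.QUIET_SITE.center_lon, ed.QUIET_SITE.center_lat,
    half_width_km=30, spacing_m=500,
    time_start="2018-01-01", time_end="2018-01-03")
field = ed.generate_flow_field(ed.QUIET_SITE, grid, seed=1)

# release 2000 particles under the delayed-decay scenario, track 24 h
event = ed.build_release_schedule(
    [(2018, 1)], 2.0, [ed.QUIET_SITE],
    [ed.DecayScenarioSpec(kind="delayed")])[0]
cfg = ed.SimulationConfig(n_particles=2000, seed=1)
traj = ed.run_event(event, field, cfg)

metrics = ed.compute_metrics_table(
    traj, {event.event_id: (event.release_lon, event.release_lat)})
print(metrics.loc[metrics.hour.isin([0, 6, 24]),
                  ["hour", "n_alive", "mean_distance_km", "hull_area_km2"]])
```

prints

```
    hour  n_alive  mean_distance_km  hull_area_km2
0    0.0     2000          0.000000       0.000000
6    6.0     5971          1.639038       1.754199
24  24.0      840          1.569917       4.528557
```

— the particle count triples by hour 6 (delayed growth phase: 2000 →
5971), then exponential decay at the field temperature (12 °C,
k ≈ 0.106 h⁻¹) reduces the plume to 840 particles by hour 24 while the
hull keeps spreading under tide and diffusion. Decay-model fitting works
the same way from the command line:

```sh
edna-dispersal synth-decay --noise-cv 0.2 --seed 1 --out series.csv
edna-dispersal fit-decay --input series.csv --form second --seed 1
edna-dispersal classify --input series.csv
```

The half-life helper reports what each scenario implies: the biphasic
mixture (0.7 @ 0.50 h⁻¹ + 0.3 @ 0.013 h⁻¹) halves at ≈ 2.41 h, a pure
exponential at k = 0.1083 h⁻¹ at ≈ 6.4 h, and the delayed scenario —
which first triples — only at ≈ 22.8 h (at 12 °C).

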