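# carbfact

Fuzzy-logic susceptibility mapping of the four shallow-water marine
carbonate factories — **biochemical** (ooid/microbial precipitation in very
warm, hypersaline waters), **photozoan-T** (tropical coral-reef systems),
**photo-C** (warm-temperate red-algal/seagrass carbonates) and
**heterozoan-C** (filter-feeder "background" carbonates) — from gridded
seasonal sea-surface conditions.

The package is for carbonate sedimentologists and (paleo)oceanographers who
want to map where each factory's environmental niche is realized on a
regular lat–lon grid, calibrate the niche functions from an observed factory
distribution, and score a prediction cell by cell against observations.

## Model

Each factory's susceptibility of occurrence at a grid cell is a weighted
overlay of fuzzy membership values,

    F(carb) = a·f(z) + b·f(SST) + c·f(SSS) + d·f(P),    a + b + c + d = 1,

where z is bathymetry, SST sea-surface temperature (°C), SSS the
sea-surface salinity reclassified into eight ordinal classes, and P marine
primary productivity measured as absorption due to phytoplankton (m⁻¹).
Terrigenous-influenced and deep-water cells are masked out; f(z) is the
indicator of the factory's depth interval (0–100 m or 0–200 m). The
membership forms are

* Gaussian          f(x) = exp(−S (x − MP)²)
* Near-Gaussian     f(x) = 1 / (1 + S (x − MP)²)
* Sigmoid (large)   f(x) = 1 / (1 + (x/MP)⁻ˢ)

with mid-point MP and spread S. MP is the mean of the lower and upper
environmental thresholds (or the distribution mode when only one threshold
exists); S is fixed by requiring f(threshold) = ½. Thresholds come from
seasonal percentile summaries of the environmental values under observed
factory footprints (1st/99th percentiles for SST and salinity, 5th/95th for
absorption), with warm-season statistics giving the *production* threshold
and cool-season statistics the *persistence* threshold. A factory is
present where F strictly exceeds its final threshold; competing factories
are resolved by the largest margin F − threshold, and heterozoan-C acts as
the background factory, filling unclaimed cells whose seasonal-mean
absorption is at least 0.01 m⁻¹. Inter-parameter weights can be derived
from a pairwise-comparison matrix by the analytic hierarchy process
(`carbfact.ahp`); the shipped defaults carry the full published-style
parameterization out of the box.

A deterministic synthetic-world generator (`carbfact.synthetic_world`)
produces environmental stacks with the structure the model assumes — zonal
SST gradient with poleward-growing seasonality, a hypersaline marginal
gulf, upwelling stripes, shelves, terrigenous bands — so the whole chain
runs and is testable without any satellite downloads.

## Worked example

```sh
carbfact simulate --out demo/sim --seed 42
carbfact predict  --env demo/sim/env.nc --out demo/pred
carbfact evaluate --observed demo/sim/truth.nc \
                  --predicted demo/pred/factory_map.nc \
                  --env demo/sim/env.nc --out demo/eval
```

prints `global accuracy: 100.00%`: predicting with the same parameters that
generated the truth map reproduces it exactly, and `demo/eval/anomalies.csv`
shows zero over- and underestimated cells per factory. The calibration
arithmetic of the tropical factory can be checked directly:

```python
>>> from carbfact import default_params
>>> from carbfact.calibration import compute_midpoint
>>> from carbfact.membership import evaluate
>>> compute_midpoint((24.15, 17.65), 30.5)   # production/persistence -> MP
25.7
>>> spec = default_params()["photozoan_T"].sst
>>> round(evaluate(spec, 30.5), 4)           # membership at the 30.5 degC maximum
0.501
>>> round(evaluate(spec, 20.9), 4)           # ... and at the averaged minimum
0.501
```

Both printed thresholds sit on the half-susceptibility crossing of the
shipped Gaussian (MP 25.7, S 0.03), i.e. the f(threshold) = ½ calibration
rule holds at both ends of the niche.

## Layout

- `carbfact.grid_io` — lat–lon grids, NetCDF IO, co-registration, salinity
  reclassification, terrigenous/bathymetric masks
- `carbfact.membership` — the fuzzy membership forms
- `carbfact.calibration` — footprint extraction, percentile summaries,
  thresholds, mid-points and spreads
- `carbfact.ahp` — analytic-hierarchy-process weighting
- `carbfact.factory_model` — susceptibility overlay, thresholding,
  combination; default parameterization and YAML configs
- `carbfact.evaluation` — cell-by-cell agreement and anomaly accounting
- `carbfact.synthetic_world` — seeded synthetic environments and truth maps
- `carbfact.cli` — `simulate | analyze | calibrate | predict | evaluate`

See `docs/methods.md` for the modelling choices and their rationale.
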