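# landalloc

Multi-objective, multi-scenario land allocation for conservation and
development on gridded planning units.

Meeting 2050 demand for food and renewable energy while conserving land for
biodiversity, carbon and Nature's Contributions to People (NCP) forces
competing claims on the same landscapes. `landalloc` implements a
country-level spatial optimisation framework for exploring that tension:
each grid cell (planning unit) is assigned to at most one of seven zones —
conservation or a development sector (food crops, energy crops, PV solar,
CSP, wind, hydro) — by mixed-integer linear programming, under three
planning orchestrations:

* **Production-First** — development is sited first (minimum-set: meet all
  sector demand at least cost), conservation gets the remaining land;
* **Nature-First** — conservation is sited first, development gets the rest;
* **Multi-Sector** — all seven zones are allocated concurrently in one
  problem.

Each scenario runs two ways: conservation constrained to 30% of each
country's land (existing protected areas included), or unconstrained. The
package is aimed at conservation planners and land-use researchers who want
to prototype and stress-test cross-sector planning logic.

## The model in brief

For cells *i*, zones *z* and features *j* with amounts *a(i, j, z)* and
targets *T_j*:

* minimum set: min Σ c(i,z)·x(i,z)  s.t.  Σ a(i,j,z)·x(i,z) ≥ T_j ∀j,
  Σ_z x(i,z) ≤ 1 ∀i, x binary;
* minimum shortfall: min Σ_j s_j / T_j  s.t.  held_j + s_j ≥ T_j, s_j ≥ 0,
  Σ c·x ≤ B (B effectively infinite simulates no budget).

Development cost per cell is `1 + (1 − DPI) + third-term`, where DPI is the
sector's development-potential index and the third term is the
protected-area indicator (Production-First) or a conservation-value
composite of range-size rarity, carbon and summed NCP (Nature-First,
Multi-Sector). Species targets scale from 100% of habitat (ranges below
1,000 km²) to 10% (above 250,000 km²), log-linearly in between; carbon and
NCP targets are 90% of current country amounts; sector targets come from
regional demand disaggregated by country market shares. Two loops handle
unattainable instances: a target-scaling loop drives conservation to 30% of
land, and a demand-decrement loop shrinks infeasible development demand —
with achievement always reported against the original targets. See
`docs/methods.md` for the full treatment.

A first-class synthetic-world generator (`landalloc.synthworld`) produces
deterministic worlds with the statistical structure the analysis assumes —
autocorrelated asset fields, compact species ranges with a heavy-tailed
size distribution, contiguous countries, clumped protected areas and
calibrated demand — so the whole pipeline runs without any external data.

## Worked example

```python
from landalloc.synthworld import SyntheticWorldConfig, generate_world
from landalloc.targets import build_targets
from landalloc.scenarios import ScenarioConfig, run_nature_first
from landalloc.evaluate import targets_met

world = generate_world(SyntheticWorldConfig(seed=1))   # 40x40 cells, 3 countries
targets = build_targets(world)
result = run_nature_first(world, targets, ScenarioConfig(scenario="nature_first"))

rows = targets_met(result, targets)
for kind in ("species", "ncp", "sector"):
    sub = rows[rows["kind"] == kind]
    print(kind, f"{100 * sub['met'].mean():.1f}% of targets met")
print({k: v for k, v in result.category_areas_km2().items() if v})
```

prints

```
species 100.0% of targets met
ncp 100.0% of targets met
sector 5.6% of targets met
{'unallocated': 3575.0, 'existing_conservation': 4425.0,
 'new_conservation': 27675.0, 'food_crops': 975.0, 'energy_crops': 300.0,
 'pv_solar': 1425.0, 'csp': 625.0, 'wind': 500.0, 'hydro': 500.0}
```

Conserving first meets every species and NCP target but leaves little
prime land for development (5.6% of sector targets met on this world);
running `run_production_first` on the same world meets 100% of development
targets instead, at the price of higher species and carbon exposure — the
central trade-off the three scenarios make explicit.

The same pipeline is scriptable from the shell:

```sh
landalloc synth --seed 1 --out world/
landalloc targets world/ --out targets.csv
landalloc run world/ --targets targets.csv --scenario multi_sector --constrain30 --out run/
landalloc evaluate world/ run/ --targets targets.csv --out evaluation.csv
landalloc overlay world/ --targets targets.csv --out conflict/
landalloc colocate world/ --targets targets.csv --out colocation.csv
```

## Layout

| Module | Role |
| --- | --- |
| `landalloc.grids_io` | grids, layers, TIFF/CSV I/O, availability mask, sparse amounts |
| `landalloc.synthworld` | synthetic-world generator and world-directory I/O |
| `landalloc.targets` | feature types, demand tables, target rules |
| `landalloc.allocator` | zoned MILP construction and solving (HiGHS) |
| `landalloc.scenarios` | the three scenario orchestrations and both loops |
| `landalloc.evaluate` | targets met, efficiency, exposure, conflict, co-location |
| `landalloc.cli` | `landalloc` command-line interface |
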