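# Methods

## The planning problem

`landalloc` allocates gridded planning units (cells) among seven mutually
exclusive land uses: conservation and six development sectors — food crops,
energy crops, photovoltaic solar (PV), concentrated solar power (CSP),
onshore wind, and hydro power. Each cell carries amounts of *features*:
species habitat (area of habitat intersected with projected future climatic
suitability), vulnerable carbon, Nature's Contributions to People (NCP)
indices, and per-sector potential yields (GW of capacity for the energy
sectors, tonnes of dry matter for the crop sectors). All allocation is done
per country; regional sector demand is first disaggregated to countries by
market share.

Cells above 80% human modification are unavailable (the threshold is read
strictly: a cell with HM = 0.80 remains available, HM > 0.80 does not).
Existing protected areas are always locked in to conservation in
conservation problems. Co-location of sectors within one cell is not
modelled; each cell receives at most one land use.

## Objectives

Two integer-programming objectives, solved with the HiGHS branch-and-cut
backend via `scipy.optimize.milp` to a 1% relative optimality gap by
default:

* **Minimum set**: minimise Σᵢ Σ_z cᵢ_z xᵢ_z subject to held_j ≥ T_j for
  every feature target j, Σ_z xᵢ_z ≤ 1 per cell, and lock constraints.
  Infeasibility is a reported status, not an exception.
* **Minimum shortfall**: minimise Σ_j s_j / T_j with held_j + s_j ≥ T_j,
  s_j ≥ 0 and a budget Σ c·x ≤ B. Targets with T_j = 0 carry no shortfall
  term. An "effectively infinite" budget (total cost of all cells in all
  zones, plus one) makes the budget constraint slack, so the solver meets
  every individually attainable target.

Because cells beyond those needed to reduce shortfall are free under an
infinite budget, the min-shortfall objective is degenerate in the
selection. A tie-break term (weight 10⁻⁷ on total cost) is added so equal-
shortfall optima resolve to the cheapest, most parsimonious selection; the
weight is small enough that it cannot trade against any meaningful
shortfall difference at the problem sizes used here.

### Numerical safeguards

Uniform conservation costs make minimum-set instances highly symmetric;
occasionally HiGHS spends long proving the last percent of the gap. Each
solve therefore carries an optional wall-clock cap (default 5 s in scenario
runs, configurable): when the cap is hit, the incumbent — always
integer-feasible, hence meeting all hard constraints — is accepted and the
allocation status records `time_limit` instead of `optimal`/`gap_ok`.
Reported achieved gaps are the solver's own bound.

## Costs

Development cost per cell is the sum of three equally weighted [0, 1]
components: a ubiquitous land cost of 1; siting feasibility, the complement
of the sector's development-potential index (1 − DPI); and a third,
scenario-dependent term. In Production-First the third term is the
protected-area indicator (value 1), letting development buy into current
conservation areas at a penalty and revealing risk to them. In Nature-First
and Multi-Sector it is the conservation-value composite: the mean of
range-size rarity (Σ_species cell amount / global range), vulnerable
carbon, and summed NCP, each rescaled to [0, 1] by its world maximum (an
all-zero component contributes zero). Conservation cells cost 1 each, so
minimum-set conservation minimises area.

## Targets

* **Species** — a global percentage from range size: 100% of habitat below
  1,000 km², 10% above 250,000 km², log-linear in between (all four
  constants configurable). The percentage is applied to each country's
  retained habitat; countries without the species get no target.
* **Carbon and NCP** — 90% of the current country amount, per layer.
* **Development** — regional demand × country market share; regional totals
  are preserved exactly because shares sum to one within each region.

Conservation targets in minimum-set problems are additionally capped at the
amount actually present among the problem's candidate cells. Without the
cap, a feature whose country amount partly sits on unavailable (HM > 0.8)
or previously developed cells would make the problem infeasible outright;
with it, the solver conserves everything reachable and the gap to the
original target is reported as shortfall. All achievement metrics are
always evaluated against the original, uncapped, unscaled targets.

## Scenarios

* **Production-First**: one six-sector minimum-set problem on sector demand
  (demand-decrement loop on infeasibility), then conservation on the
  remaining land — minimum shortfall with infinite budget, or the 30% loop.
* **Nature-First**: conservation first (minimum set on full targets, or the
  30% loop), then development as minimum shortfall on the remaining land,
  with protected areas and the conservation solution unavailable.
* **Multi-Sector**: one joint seven-zone minimum-shortfall problem per
  country; under the 30% constraint the conservation zone also carries a
  hard per-country area cap.

### The 30% loop

Countries aim to conserve 30% of their land (including existing protected
areas). All conservation targets are multiplied by one common factor,
starting at 0.10 and raised by a fixed increment (default 0.01 of the
factor) with a solve at each step, until the selected conservation area
first reaches 30% of country land or the factor reaches 1. Both the last
under-the-budget solution and the first crossing solution are retained;
the under-shooting one is reported by default. A country whose protected
areas already cover 30% or more gains no new conservation. A single common
factor (rather than per-feature scaling) keeps the loop a one-parameter
family.

### The demand-decrement loop

If the development minimum-set problem is infeasible (demand exceeding what
the available land can yield), all development targets are multiplied by
(1 − k·0.05) for k = 1, 2, … until a solve succeeds; a factor reaching zero
returns the empty development solution. Post-hoc evaluation always uses the
original targets, so decremented runs report less than 100% achievement.

## Evaluation

* **Targets met** — species assessed at the species level (held and target
  summed over countries); NCP, carbon and sectors per country. A zero
  target is trivially met.
* **Land efficiency** — allocated sector area per unit of achieved
  production (km²/GW, km²/tonne), pooled and per country; undefined (NaN
  with a reason) when achieved production is zero.
* **Species exposure** — a species is exposed when at least 10% of its
  global range (boundary inclusive) lies inside the development footprint.
  The denominator is the global range; mean overlap statistics are computed
  over exposed species by default (both switchable).
* **Carbon exposure** — carbon summed over development cells, in Mt.
* **Conflict overlay** — four runs (Production-First and Nature-First, each
  with and without the 30% budget) overlaid per cell. The development
  footprint is the union of the two Production-First footprints. Precedence,
  strongest last: conservation classes < existing protected areas <
  development < conflict-with-full-conservation < conflict-with-30%-
  conservation-or-protected-areas. The classes partition the grid.
* **Co-location overlap** — crops (food + energy), PV and wind prioritised
  independently (no mutual exclusivity) with the Production-First cost
  structure; pairwise footprint overlaps reported as a percentage of each
  side's area.

## The synthetic world generator

The generator emulates the statistical structure of the continental raster
stacks this kind of analysis consumes, so every stage is testable without
external data:

* **Fields** — carbon, NCP, DPI, HM and yields derive from FFT-filtered
  Gaussian random fields with a configurable correlation length (default 6
  cells), exponentiated for non-negative assets, logistic-squashed for DPI,
  mean-shifted and clipped for HM (default mean 0.25). Hydro potential is
  sparsified to its best fifth of cells, reflecting how strongly that
  sector is siting-constrained.
* **Species** — range areas are log-normal (median 1,500 km², σ_log = 1.2),
  clipped to [one cell, 40% of land]; ranges grow as randomised-BFS blobs,
  giving compact contiguous habitat. Future suitability is an independent
  thresholded field covering the configured overlap fraction (default 0.7)
  of the grid; species whose habitat misses it entirely keep their current
  habitat. Occupancy is binary; per-cell habitat is cell area × occupancy.
* **Countries** — multi-source flood fill from random seeds over the
  largest connected land component: contiguous partitions, grouped
  round-robin into regions.
* **Protected areas** — the top fraction (default 0.12) of a smooth field,
  giving clumped reserves with an exact cell count.
* **Demand** — per region and sector, a configured fraction (default 0.10)
  of the total potential yield on available cells; fractions above 1
  deliberately produce demand-infeasible instances. Country shares follow
  supply shares with multiplicative noise, renormalised to sum to one.
* **Determinism** — one integer seed; each component draws from a fixed,
  labelled substream, so generation order cannot change results and equal
  seeds give bit-identical worlds.

What the generator does **not** emulate: real geography and topography,
spatial correlation *between* layers (carbon–biodiversity covariance, DPI
concentrated near infrastructure), realistic SSP demand magnitudes, or
fractional habitat occupancy. Passing tests therefore demonstrate the
correctness and contracts of the pipeline — not that real-world headline
quantities would be reproduced, which depend entirely on the input data.

## Problem sizes and defaults

Default study worlds are 40×40 cells of 25 km² (5 km resolution), 3
countries in 2 regions, 30 species, 1 carbon + 6 NCP layers, all six
sectors. At this size a sequential scenario solves in seconds and a joint
constrained scenario in about a minute. The acceptance script runs all six
scenario variants on one such world with 0.05 target increments in the 30%
loop and a 2 s per-solve cap. Tests use 16–40 cell grids, chosen so
exhaustive enumeration (≤ ~20,000 assignments per instance) can serve as an
independent oracle for the solver.

## Known limitations

* Minimum-shortfall selections are unique only up to the tie-break; tests
  compare objective values, not selections.
* The 30% loop reports the under-shooting iterate; if even the 10% floor
  solve overshoots the land budget (possible when protected areas sit just
  below 30%), the crossing iterate is returned and the trace records it.
* The conflict overlay's precedence order is a reporting convention; other
  conventions would shade overlapping cells differently.
* Demand disaggregation assumes market shares are exogenous inputs; they
  are not derived from any within-package projection.
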