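# Methods

## Model

The package plans production of a cultivated resource that grows in a
facility for a residence (growth) time `t` and must then survive in the
wild. Demand `d_i` at cluster `i` is stated in *surviving* units per
year; the post-deployment survival fraction `P(t)` converts it into a
production requirement `Σ_j X_ij = d_i / P(t)`. The decision problem —
which facilities to open, how to allocate production, how many vessel
trips to run, and what growth time to use — is a mixed-integer
*nonlinear* program only through `P(t)`; at fixed `t` it is linear.

### Survival curves

Four parametric forms, each truncated to `[0, p_max]` (values at or
below zero clamp to 0, values above the ceiling clamp to `p_max`):

| form | `P(t)` before truncation | role of `c` | role of `t0` |
|---|---|---|---|
| asymptotic | `p_max − 1/(c(t−t0) + 1/p_max)` | curvature scale | x-intercept |
| linear | `c(t−t0)` | gradient (1/yr) | x-intercept |
| logistic | `p_max / (1 + e^{−c(t−t0)})` | steepness (1/yr) | inflection point |
| pseudo-gamma | `c(t−t0)·e^{−c(t−t0)}` | peak sharpness | x-intercept |

The pseudo-gamma form peaks at `t0 + 1/c` and then decays, modelling
units that acclimate to facility conditions and fare worse in the wild
when held too long. An optional floor `p_min` (default 0) is applied as
a lower clamp after truncation. A cutoff `pmin_allow` (default 1e-4)
excludes growth times whose survival is so small that the implied
production `D/P(t)` becomes astronomically large; excluded grid points
are reported as such, never silently dropped. The default cutoff keeps
the entire base grid (asymptotic, c=25, t0=0, p_max=0.1, t ≥ 0.02)
admissible: `P(0.02) ≈ 0.0048 > 1e-4`.

### Costs

Annualized cost has four components. Capital sums are converted to
annual payments with the capital recovery factor
`CRF = i/(1−(1+i)^{−n})` (defaults: i = 5%/yr, n = 25 yr, CRF ≈ 0.07095).

* fixed capital: `CRF · c_f_cap` per open facility ($10M default);
* variable capital: facility floor area follows Little's law — average
  in-process inventory is throughput × residence time, `t·X` units, at
  `a` m²/unit (8.05 m² per 24,000 units) — priced at `c_v_cap`
  ($45,000/m²) and amortized, giving `CRF·c_v_cap·a·t·X`;
* operating: `c_f_op` ($2.56 per unit-year of residence) on the same
  inventory, `c_f_op·t·X`;
* transport: per-trip cost `c_ij^T = c_d_op · (2·distance(j, i) +
  intra-cluster allowance_i)` at `c_d_op` = $100/km, times integer
  trips `T_ij` of at most `s_c` = 432,000 units each.

The per-unit residence cost `t·(CRF·c_v_cap·a + c_f_op)` is the form of
the objective's production term; it reproduces the benchmark cost split
(53% operating / 23% transport / 22% variable capital / 2% fixed
capital of $172.5M/yr at 356.2M units, t = 0.10, five facilities),
which is the package's consistency anchor for the cost model.

### Demand geometry and clustering

A reef of surveyed area `A` km² is modelled as a disc of radius
`r = √(A·10⁶/π)` m. The restoration atoll is the annulus of width
`r_width` (20 m) centred on the perimeter; demand is planting density
`d_c` (1 coral/m²) × atoll area. Reefs with `r ≤ 100` m restore the
full disc out to the band's outer edge instead (the annulus inner
radius would otherwise be ill-defined or negative for tiny reefs).

Clustering sweeps reefs north → south (ties: longitude, then id),
greedily accumulating adjacent reefs while cumulative annual demand
stays within one vessel load `s_c`; an oversize reef forms a singleton.
The cluster's coordinates are the unweighted mean of member
coordinates — adequate at sub-degree cluster extents — and its
intra-cluster allowance is a round-trip star tour, `2·Σ` centroid→member
great-circle distances, which grows with member count and is cheap to
compute. The capacity rule uses *annual* demand (one vessel load as the
service batch); whether the batch should instead scale with growth time
is not determined by the source material, and the annual rule
reproduces the benchmark scale (50 reefs → ~20 clusters).

Distances are great-circle on a sphere of radius 6371 km; the error
against ellipsoidal geodesics is far below cost-parameter uncertainty.

### The MILP and the outer search

At fixed `t̂` the model is the capacitated facility-location MILP shown
in the README. Constraint `t·Σ_i T_ij ≥ Y_j` (deployment frequency) is
gated by `Y_j`: the requirement that a facility's stock is shipped out
at least once per growth period can only apply to open facilities —
ungated it would forbid closing any site. The big-M linking constraint
uses `M = D / min{P(t) on the admissible grid}`, the largest production
any facility could ever need (exposed as `big_M`).

The outer stage enumerates `t ∈ {t_min, t_min+Δt, …, t_max}` (defaults
0.02, 1.00, 0.02 — roughly weekly resolution over a year), skips
excluded points, solves each MILP to proven optimality (`mip_gap` 0)
and keeps the incumbent under strict improvement, so the smallest
growth time attaining the minimum wins ties. `t*` is therefore exact to
±Δt/2. Production variables are continuous (fractional corals are a
flow approximation, rounded only for presentation).

## Numerical choices

* **Solver.** The inner MILP is solved by HiGHS through
  `scipy.optimize.milp`, behind a narrow model container (`MipModel`:
  cost vector, sparse constraint matrix, integrality, bounds) so
  another backend can be swapped in.
* **Variable scaling.** Inside the solver, production is expressed in
  vessel loads (`X' = X/s_c`). Raw unit counts reach 10⁸–10⁹ while
  other coefficients are O(1); that 11-order spread stalls MILP
  branch-and-bound numerics, whereas the scaled model solves each grid
  point in well under a second. Results are mapped back to units.
* **Big-M tightening.** The linking coefficient at fixed `t̂` is
  `min(M, D/P(t̂))`. Any optimal plan produces exactly `D/P(t̂)` in
  total (production is costly and demand binds), so no facility can
  optimally exceed it and the optimum is unchanged; the LP relaxation
  tightens dramatically at high-survival growth times.
* **Objective reporting.** The reported objective is recomputed from
  the extracted integer-rounded variables, so the cost breakdown sums
  to the objective to 1e-6 relative by construction.
* **Grid endpoints.** The growth-time grid accumulates `t_min + kΔt`
  with a 1e-12 tolerance so `t_max` is included exactly when it lies on
  the arithmetic grid. Trip ceilings use a 1e-9 tolerance before
  rounding up.

## Verification oracle

`brute_force_oracle` solves instances with at most 6 clusters and 6
facilities by exhaustive enumeration: every open-facility subset, every
single-facility assignment of positive-demand clusters, trips
`⌈X_i/s_c⌉`, plus top-up trips (at the facility's cheapest per-trip
cost) for any open facility short of the `⌈1/t⌉` deployment-frequency
floor. Splitting a cluster across facilities is provably never cheaper:
the residence cost term is facility-independent, `⌈a⌉+⌈b⌉ ≥ ⌈a+b⌉`
means splitting never saves trips, and any trip a split contributes to
the frequency floor is available at least as cheaply as a top-up. The
oracle shares no code with the MILP path and anchors a 100-instance
randomized equivalence test at 1e-6 relative tolerance.

## Synthetic data

The real reef registry (2,816 reefs with name, coordinates and area) is
proprietary, so `generate_synthetic_reefs` emulates its statistical
skeleton: latitudes uniform over 10°S–25°S, longitudes at a
piecewise-linear approximation of the Queensland coastline plus a
0.3°–2.0° offshore offset, areas lognormal (log-mean 1.1, log-sd 1.0,
median ≈ 3 km²). Those area parameters are chosen so a 50-reef sample
generates ≈ 7 million surviving corals/year of demand — the benchmark
scale — and the sweep yields on the order of 20 clusters at the default
vessel capacity. All randomness flows through an explicit seed.

What the synthetic field does *not* reproduce: the true registry's
spatial clumping into reef complexes, the area distribution's exact
shape, and any correlation between reef size and offshore distance.
Tests passing on synthetic fields therefore demonstrate the machinery's
correctness and the model's qualitative behaviour (directional
sensitivities, scale, termination), not the real case study's facility
identities or its $172.5M/yr optimum, which depend on the proprietary
reef subset. The closed-form benchmark quantities (survival rate,
production volumes, cost shares) are reproduced exactly because they do
not depend on the registry.

## Problem sizes used in the shipped analyses

The test suite and acceptance script run a 50-reef, 7-port instance
(≈ 18 clusters) with the full 50-point growth-time grid for the scale
check, a 25-point grid (Δt = 0.04) for the directional sensitivity
sweeps, and 100 random ≤ 4×4 instances for oracle equivalence; these
sizes solve in seconds to a few minutes on a single CPU while
exercising every code path at the benchmark's order of magnitude.

## Known limitations

* Transport is single-mode, straight-line, homogeneous-fleet; no
  truck/barge legs or heterogeneous vessels.
* Costs are homogeneous across candidate sites; real land, utility and
  labour costs differ by port.
* Survival is a deterministic function of growth time only — no
  seasonality, site dependence, species mix or uncertainty.
* The greedy latitude sweep is not an optimal clustering; better
  clustering would reduce transport distances.
* Growth time is discretized; the returned `t*` is optimal only to half
  a grid step, and no staged capacity expansion is modelled.
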