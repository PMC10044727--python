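# Methods

`larvanet` estimates the larval-dispersal connectivity of a system of 21
national marine protected areas (MPAs) on the Yellow/East China Sea shelf
from a multi-species biophysical simulation. This note documents the model,
its parameters and defaults, the numerical choices, and what the synthetic
ocean does and does not represent.

## Biophysical model

Larvae are passive particles. For each of the 14 study species, 1000
particles are released at the center of every MPA where the species occurs
(217,000 particles in total across species), at 00:00 on the middle day of
the species' spawning window, at the species' living depth. Particles drift
with the horizontal current at that fixed depth for the species' pelagic
larval duration (PLD, 7–75 days); there is no vertical migration, growth,
or swimming.

The middle day of an inclusive month window of D days is day ⌈D/2⌉, with
windows that wrap year-end (e.g. December–March) anchored so the window
starts in the reference year (default 2016); April–May therefore releases
on May 1 and December–March on January 30 of the following year.

**Mortality.** Each simulated day, every living particle independently dies
with probability 0.15 (the conventional 10–20 %/day range for early larval
stages; 15 % is the package default). The draw happens at the day boundary,
*after* that day's final recorded position, so a particle that enters an
MPA at the 24-h sample still scores the arrival even if the same day's draw
removes it. A per-step exponential-hazard variant (`mortality_mode=
"per_step"`) is available, with the per-step probability matched so daily
survival equals 0.85; both modes satisfy the (1 − rate)^d survival curve.

**Integration.** Positions advance by classical 4th-order Runge–Kutta with
a 1-hour step (recorded every 6 hours). Velocities in m/s convert to
degrees via a local equirectangular metric (111,320 m per degree latitude;
longitude scaled by cos φ), which is accurate to well under 1 % over the
24–36° N domain. On a constant field RK4 reproduces the analytic
displacement to machine precision, which the tests assert.

**Boundaries.** A particle whose next position's nearest grid node is land
*strands*: it keeps its last wet position, stops moving, and remains alive
(it can still score arrivals at that position and still dies by mortality).
A particle stepping outside the grid is flagged *dead-by-exit*, frozen at
its last in-domain position, and excluded from all later arrival counting
while staying in release denominators. At every output step
alive + dead-by-mortality + dead-by-exit = released.

## Connectivity quantities

An **arrival** is the first 6-hourly sample at which a living particle lies
inside an MPA boundary polygon (boundary-inclusive). The default counts
entries at any time during the PLD; a settlement-only mode
(`arrival_mode="end_of_pld"`) restricts to the final sample, since no
competency window is known for these species.

* **Dispersal flux** d(i) = r(i) / Σᵢ r(i), where r(i) counts arrival
  records in MPA i — the share of all arrival events landing in i. The
  released-total normalization r(i)/N_released is reported alongside as
  `d_abs`; the two differ only by the overall arrival rate.
* **Connection probability** c(i,j) = (particles released at i with an
  arrival at j) / (particles released at i). The diagonal counts presence
  in the origin polygon at any post-release sample (including t = 0), which
  makes the zero-flow identity exact; a leave-and-return-only diagonal
  would require a competency assumption the data do not support.
* **Self-recruitment** selfr(i) = c(i,i)/Σⱼ c(i,j) and **subsidy
  recruitment** subr(i) = Σ_{j≠i} c(i,j)/Σⱼ c(i,j); they sum to 1 wherever
  MPA i has any connection. The default normalizes over *outgoing*
  connections (row-wise); `orientation="incoming"` normalizes column-wise
  (replenishment received), and every output labels the orientation used.
  MPAs with no connections are flagged `defined=False` with fractions
  reported as 0, never NaN.
* **Aggregation** across species adds c-matrices with the threatened group
  and the economic group each carrying total weight 0.5, split equally
  within group (9 threatened → 1/18 each; 5 economic → 1/10 each).

## Network metrics

The MPA graph is directed: edge i→j wherever c(i,j) exceeds the edge
threshold (strictly > 0 by default); self-loops are excluded because
self-recruitment is reported separately. Edges with c ≥ 0.001 carry a
demographic-relevance flag — weaker exchange may matter genetically but not
demographically — carried as an attribute, not a filter, so threshold-style
summaries remain computable.

Degree counts *distinct* neighbors (union of in- and out-neighbors, so a
reciprocal pair adds 1); indegree/outdegree count distinct upstream and
downstream neighbors. Betweenness is the unweighted directed convention:
bc(i) = Σ_{x≠y≠i} σ\_xy(i)/σ\_xy over ordered pairs, σ\_xy the number of
fewest-hop directed paths, pairs with no path contributing 0. The tests pin
this against an exact rational-arithmetic path-enumeration oracle on 200
random digraphs of ≤ 8 nodes. A weighted variant (edge length −log c) is
available but off by default because path *multiplicity* is only well
defined in the unweighted case.

## Synthetic ocean

The generator replaces an ocean-model hindcast with the minimal kinematics
that drive the connectivity pattern:

* a straight coastline lon = 118.0° + 0.3·(φ − 24°), land to the west;
* an alongshore jet with Gaussian cross-shore profile (peak 0.15 m/s at the
  coast, e-folding width 0.8°), directed along the coast tangent:
  southward at full strength in November–April, northward at half strength
  otherwise — the seasonal reversal of the Zhejiang–Fujian coastal current,
  with the reversal months exposed as configuration because seasonal
  definitions vary;
* five depth layers (5, 15, 30, 60, 100 m) with speed attenuation 1.0,
  0.85, 0.70, 0.55, 0.40 — surface faster than depth;
* optional divergence-free eddy noise (streamfunction-derived, RMS
  0.02 m/s, seeded) so trajectories are not perfectly laminar;
* monthly snapshots over 18 months from 2016-01, linearly interpolated in
  time; 0.1° grid over 117.5–126° E, 24–36.5° N; |u|,|v| capped at 3 m/s.

What it does **not** emulate: tides, wind-driven variability, river plumes,
the Taiwan Warm Current and Kuroshio branches, curvilinear/terrain-following
grids, or any specific year's currents. Passing tests therefore demonstrate
the *machinery* (release accounting, integration accuracy, mortality
statistics, arrival counting, metric identities) under a realistic-scale
flow, not the historical connectivity of the real MPA system, whose
published values depend on a hindcast that is not redistributable.

The packaged MPA centers and MNR/SMPA designations are synthetic: the study
region's MPA centers are not published at usable precision, so the fixture
places each site slightly seaward of the synthetic coastline at latitudes
ordered by province (Jiangsu north → Fujian south), offset by its own
boundary radius so release points start in water. Areas and the
species-occurrence matrix are the published values. Boundaries default to
area-preserving circles of radius √(A/π) (vertex count 128, discretization
inflated so polygon area is within 1 %, typically 0.05 %); GeoJSON polygons
can override them per site.

## Problem sizes and determinism

The full experiment (`analysis/02_run_dispersal.py`) runs all 14 species at
1000 particles per point — the study's release scheme — in about a minute
on one core. The test suite and the acceptance script use the same machinery
at reduced particle counts (5–100 particles/point for pipeline checks;
10⁴–10⁵ particles for mortality statistics), which is ample for the 3σ
binomial tolerances they assert.

All randomness flows from explicit seeds: the field's eddy noise from its
config seed, and each species' advection/mortality from a
`SeedSequence(master_seed, species_index)` substream keyed to the species'
position in the packaged table — so a subset run reproduces the same
per-species results as a full run, and identical configs reproduce outputs
byte-for-byte. Run manifests record the config hash, seed, versions, and
the per-species particle accounting (the same numbers the conservation
invariant asserts).

## Known limitations

* No larval behavior (vertical migration, swimming, settlement competency),
  no temperature- or predation-dependent mortality.
* The equirectangular metric and regular grid are inappropriate poleward of
  ~60° or for basin-scale domains.
* Nearest-layer depth selection means species between layer centers sample
  the nearer layer's attenuation, not an interpolated one.
* Arrival detection samples positions every 6 h; a particle crossing a
  small MPA entirely between samples scores no arrival. The smallest
  packaged MPA (15.46 km², radius ≈ 2.2 km) can be crossed undetected only
  above ~0.2 m/s, at the top of the realistic speed range.
* Connectivity from spawning grounds outside the MPA system, productivity
  weighting, and fishing intensity are out of scope.
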