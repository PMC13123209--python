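# Methods

## Scope and units

`ruralct` models prehospital access to acute ischemic-stroke treatment in
a sparsely populated region: ambulance travel times over a road network,
siting of rural CT-and-thrombolysis stations, Monte Carlo
onset-to-treatment (OTT) cohorts, and transport-strategy classification
for suspected large vessel occlusion (LVO) stroke. Coordinates are planar
kilometres (no geodesy — the synthetic regions are desk-scale); road
lengths are metres, speeds km/h, and every time is minutes except the
Emberson relation, which takes hours at its boundary.

## Road network and travel times

Roads are directed weighted edges with length, speed limit, one-way flag
and optional ferry attributes. Edge traversal time is
`60 · length_m/1000 / speed_kmh`, plus a positive `crossing_min` for
ferry edges. Ferry crossing time is a fixed deterministic add-on; no
timetable waiting is modelled — a deliberate, conservative simplification
since real waiting times depend on schedules the model does not carry.
Shortest times use Dijkstra (networkx) on the directed graph; the
closest-facility field runs one reverse-graph Dijkstra per facility.

Ambulance minutes are `speed_factor ×` the speed-limit driving minutes,
default 0.8 (ambulances are faster than speed-limit driving). The factor
is applied after path search; because it is a uniform scaling it cannot
change which path, or which facility, is optimal. Cells with no route to
any facility are flagged unreachable — never a silent zero — and are
excluded from every downstream population denominator.

## Synthetic regions

The generator (`ruralct.region`) emulates the features the analysis is
sensitive to, with all randomness drawn from a single seeded Generator:

- **Towns** — centres spread by best-candidate sampling, each a small
  ring-and-spoke street cluster (a ring is occasionally one-way, which
  keeps the cluster strongly connected by construction). Pareto-weighted
  sizes give a primate-city distribution. Hospitals occupy the largest
  towns; the largest of those are EVT-capable.
- **Trunk roads** — a minimum spanning tree over town centres, subdivided
  into ~3-km segments at fast speeds.
- **Rural branches** — slow 2.5–5.5-km chains leaving the trunk roughly
  away from the region centre, occasionally via ferries; branch tips are
  extended until the rural tail holds at least twice as many settlement
  nodes as candidate CT sites and reaches > 110 ambulance-minutes, so
  that siting is a genuine selection problem rather than one station per
  settlement.
- **Population** — square grid cells (`cell_size_m`, default 250 m, area
  0.0625 km²). Allocation happens *after* travel times are computed:
  `rural_tail_fraction` of residents (default 12%, within the 8–18% band
  typical of national rural-share statistics) goes to settlement nodes
  strictly beyond the 70-min threshold, `town_population_fraction`
  (default 70%) to Gaussian-peaked town blocks, and the remainder to
  accessible countryside. Rural settlement weights decay exponentially
  with remoteness (e-folding 45 min beyond the threshold), reflecting
  that fewer people live deeper into remote valleys. Integer populations
  use largest-remainder apportionment, so totals are conserved exactly
  and the realized rural share matches the target up to rounding — the
  calibration is by construction, not tuning.
- **Candidate CT sites** — sampled among rural-branch nodes with weights
  proportional to local population (a proxy for public buildings with
  road access). Candidates carry a 30-min door-to-needle (telestroke
  supervision) and a 50-min door-in-door-out; hospitals draw door-to-
  needle from 25–40 min with door-in-door-out = DTN + a fixed 30-min
  needle-to-door-out, and EVT centres draw door-to-groin from 60–90 min.

Outputs (`network.geojson`, `cells.geojson`, `facilities.csv`) are
written with sorted keys and fixed rounding, so one seed yields
byte-identical files. A draw whose hospitals cannot reach the bulk of the
population is retried a bounded number of times, then fails hard.

What the generator does **not** emulate: real topography and coastline
geometry, elevation/weather effects, time-dependent traffic, helicopter
transport, and the true spatial autocorrelation of Norwegian settlement.
Passing tests therefore demonstrate correctness of the machinery and its
invariants under the assumed structure, not forecasts for any real
region.

## Station siting

The rural subgroup is the set of cells with baseline ambulance minutes
strictly > 70. The default objective is population-weighted total minutes
saved; cells keep their incumbent hospital whenever it is nearer, so a
station can never worsen access. A coverage objective
(population brought within the threshold) is available as a config enum
for sensitivity runs. Greedy forward selection (no swaps) re-evaluates
the marginal gain after each pick, breaking ties by lowest candidate id;
both objectives are monotone submodular, giving the (1 − 1/e) greedy
guarantee that the test suite checks against exhaustive enumeration on
small instances. `exact_deploy` refuses instances beyond a configurable
subset-count cap (default 200,000).

## Cohort simulation

Patient cells are drawn with probability proportional to population from
the rural subgroup (full-population sampling is the caller's choice by
passing different cells). Non-transport OTT components are independent
gammas, sampled in a fixed order after the location draw so that two
scenarios sharing a seed share their random numbers (common random
numbers; scenario contrasts are then purely due to travel times, and
benefit is monotone pathwise). Defaults (shape, scale in minutes):

| component | α | β | mean | median |
|---|---|---|---|---|
| onset-to-alarm | 2.0 | 28 | 56 | ~47 |
| alarm-to-scene | 4.0 | 4 | 16 | ~15 |
| on-scene | 5.0 | 3.2 | 16 | ~15 |
| door-to-needle | 7.0 | 4.3 | 30 | ~29 |

These were calibrated once so the median of the summed components is
~110 min (the registry-based non-transport share of OTT); the calibration
is asserted as a test with a ±5-min band. Zero-variance
`ConstantComponent`s (which burn one gamma draw to keep streams aligned)
support exact degenerate-limit checks.

Treatment: treated iff OTT ≤ 270 min; OR for good outcome (mRS 0–1) is
`exp(0.2749 − 0.1458 (t − 4.02)/1.228)` at t hours, and exactly 1 for
untreated patients, so every cohort obeys the mixing identity
`mean OR = (1 − u) · mean(OR | treated) + u` with u the untreated
fraction. Threshold fractions use strict inequalities (< 180, > 270).
Scenario comparison uses a pooled two-proportion z-test (statsmodels) for
the threshold fractions — identical cohorts short-circuit to p = 1, where
the pooled statistic would be 0/0 — and a seeded paired bootstrap
(2000 resamples, percentile 95% CI) for the mean-OR difference. The
reporting helper converts minutes saved to healthy-life days at 1.8
days/min.

## LVO strategy maps

For each cell, the mothership option (direct to nearest EVT centre) is
compared with drip-and-ship via every thrombolysis-capable site. Needle
time = prehospital median (onset-to-alarm + alarm-to-scene + on-scene
medians) + transport + site door-to-needle; drip-and-ship groin time adds
the site's door-in-door-out (50 min at CT stations; DTN + 30 at
hospitals), the transfer leg and the EVT centre's door-to-groin.

The published transport-model outcome equations are proprietary, so the
probability curves are the package's own: thrombolysis probability is the
odds transform of the Emberson OR around an untreated baseline p₀ = 0.30
(window 270 min), and EVT probability decays linearly from 0.70 at ≤ 60
min to 0.30 at the 360-min window, returning p₀ beyond it. The floor
equals p₀ so the curve is continuous and non-increasing across the window
edge. The slopes were chosen so the two weighted marginal effects
(0.145 · ∂p_EVT/∂t vs 0.31 · ∂p_tPA/∂t) are of comparable magnitude,
which is what makes the decision surface non-trivial; the classification
depends only on these monotone relative comparisons, and no constant
claims to reproduce the proprietary model. A configurable additive bonus
for EVT outcome after prior thrombolysis defaults to 0 (no claimed
synergy).

Per cell, the best option per strategy *class* (mothership,
drip-via-hospital, drip-via-CT) is ranked; the label is the top class, or
`near_equivalent` when the top two classes differ by less than ε
(default 0.01 absolute probability — the map "spotting" has no canonical
numeric threshold), with exact ties resolved mothership >
dripship_hospital > dripship_ct (fewer handovers at equal expected
outcome). Cells without a finite route to an EVT centre are `excluded`.
Since adding a drip site leaves the mothership and hospital scores
unchanged and can only raise the best competing score, mothership and
dripship_hospital areas are non-increasing under deployment — the
dominance property the acceptance suite checks on seeded fixtures.

## Orchestration, seeds and problem sizes

`run_pipeline` derives per-stage seeds as
`SeedSequence([global_seed, stage_index])` (stage 0 region, 1 cohorts,
2 bootstrap), reduced below 2³¹; all scenarios share the cohort seed
(common random numbers). Reports recompute every printed percent from
their own counts with half-away-from-zero integer rounding, and the
percent-change helper signs the rounded magnitude of
`100·|after − before|/before`.

Default problem sizes — a 120 × 120 km region, ~10² cells beyond the
threshold, 10³-patient cohorts, ≤ 30 candidate sites — were chosen so a
full pipeline run completes in about a second while every statistical
property the suite asserts (calibration bands, binomial CIs, submodular
bounds) is resolvable at those n; the same machinery scales to larger
specs by changing the `RegionSpec` counts.

## Known limitations

- Greedy siting carries only the (1 − 1/e) guarantee; the proprietary
  location-allocation tooling used in national studies may differ in
  objective and decay, so site-for-site agreement is not claimed.
- One small region cannot reproduce national geography; in particular the
  compression of benefit between k = 10, 20, 30 on the default region is
  steeper than on a country-sized network where candidates are scarcer
  relative to settlements.
- No helicopter transport, capacity constraints, staffing, or
  cost-effectiveness modelling.
- Outcome curves for the LVO decision are stylised monotone stand-ins
  with configurable constants, suitable for relative comparisons only.
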