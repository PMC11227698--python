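# Methods

## The model

`stroketriage` is a deterministic, minute-resolution timeline model of
prehospital care for suspected anterior large-vessel-occlusion (aLVO)
stroke in rural regions. Five transport strategies are compared on a common
scenario:

| Strategy | Route | Helicopter |
|---|---|---|
| `ALVO_DISPATCH` | scene → CSC by air | dispatched in parallel at call time |
| `MS_AIR` | scene → CSC by air | requested after EMS reaches the scene |
| `MS_GROUND` | scene → CSC by ambulance | — |
| `DNS_AIR` | scene → PSC by ambulance, PSC → CSC by air | interhospital only |
| `DNS_GROUND` | scene → PSC → CSC by ambulance | — |

Every milestone is the cumulative sum of named segment durations along the
strategy's chain, measured in real-valued minutes from symptom onset:

    call        = onset_to_call
    ems_dispatch = call + call_to_ems_dispatch
    ems_at_scene = ems_dispatch + ems_base_to_scene

and so on per strategy. The single non-additive step is the
**parallel-dispatch rule** of `ALVO_DISPATCH`:

    depart_scene = max(ems_at_scene + on_scene, hems_at_scene)

If the helicopter lands during on-scene care, departure happens when care
is complete (handover is absorbed into the on-scene interval; the crews
work jointly); if it lands later, departure is its arrival, because the
patient is already packaged. No separate handover term is added in this
strategy — that is the only composition consistent with joint on-scene
care under parallel dispatch. In `MS_AIR`, by contrast, the helicopter is a
secondary request: EMS works alone, requests the helicopter
`secondary_request_delay` minutes after arrival, waits
`hems_secondary_response` minutes for it, and hands the patient over
(`handover_ems_hems`), which is what inflates the on-scene interval.

Treatment endpoints:

- direct-to-CSC strategies (`ALVO_DISPATCH`, `MS_*`):
  `time_to_ivt = arrival_csc + door_to_needle`,
  `time_to_evt = time_to_ivt + needle_to_groin`;
- drip-and-ship (`DNS_*`): `time_to_ivt = arrival_psc + door_to_needle`,
  `time_to_evt = arrival_csc + door_to_groin`.

Deltas are reported as `other − ALVO_DISPATCH` (positive = parallel
dispatch faster). Winners per endpoint break ties in the fixed order
aLVO > MS air > MS ground > DnS air > DnS ground; the ordering is a
declared convention, not a clinical claim.

### Modeling choices that were genuinely open

- **HEMS dispatch anchor.** In the reference case the helicopter is
  dispatched 2 min after ground EMS (the dispatcher completes the aLVO
  query while EMS is already rolling). We anchor `hems_dispatch` to
  `ems_dispatch + ems_dispatch_to_hems_dispatch`. Anchoring to call
  receipt (+5 min) reproduces the same case numbers; the EMS-dispatch
  anchor reflects the operational sequence (standard assessment → EMS
  dispatch → aLVO query → HEMS dispatch).
- **Secondary helicopter response.** The 17-minute request-to-arrival
  interval of `MS_AIR` is a single opaque parameter; dispatch handling and
  flight are not separated because no decomposition is observable at the
  timeline level.
- **No PSC wait in `DNS_AIR`.** Departure from the PSC is
  `ivt + needle_to_door` exactly; the transfer helicopter is assumed
  pre-positioned. A waiting time must be modeled by enlarging
  `needle_to_door`.
- **Ties in `max()`** resolve to the shared value; no epsilon.
- **Rounding** happens only at render time (half-up, default integer
  precision), never during computation, so the integer case fixture
  round-trips exactly.

## Default parameters

Care intervals follow national target times and stroke-network empirical
values; travel times default to the reference rural case (all minutes):

| Parameter | Default | Meaning |
|---|---|---|
| `on_scene` | 30 | EMS arrival → ready to depart |
| `door_to_needle` | 30 | hospital arrival → IVT start (PSC and CSC) |
| `needle_to_door` | 30 | IVT start → PSC departure (drip-and-ship) |
| `door_to_groin` | 60 | CSC arrival → puncture (drip-and-ship) |
| `needle_to_groin` | 60 | IVT start → puncture (direct-to-CSC) |
| `secondary_request_delay` | 20 | EMS arrival → helicopter request (MS air) |
| `handover_ems_hems` | 15 | scene handover (MS air) |
| `onset_to_call` … travel fields | case values | 24/3/2/10/12/17/14/50/20/38/11 |

## Routing layer

Real deployments obtain leg times from road-network routing with empirical
speed profiles. Here a leg time is either (a) a measured value from a
`TravelTimeTable` override — always used verbatim when present — or (b) a
linear model

    time_min = 60 · circuity · haversine_km / cruise_kmh + overhead_min

with great-circle distance on a sphere of radius 6371.0088 km (ellipsoidal
corrections are ≪ 0.5 %, irrelevant at minute resolution). The circuity
factor converts air-line to road distance (fixed at 1 for flight); the
overhead is per-leg mobilization (ground) or take-off + landing (air).
Defaults for synthetic regions — ground 90 km/h, circuity 1.4, overhead
1 min; air 220 km/h, overhead 8 min — roughly reproduce the case legs and
are config-overridable.

`calibrate_speed_model` fits slope and intercept by ordinary least squares
(`numpy.polyfit`), clipping a negative intercept to zero and refitting the
slope through the origin. Circuity and cruise speed are not separately
identifiable from time observations; circuity is taken as given and the
cruise speed absorbs the slope. Two observations give exact two-point
interpolation (e.g. the case's two measured flight legs, 26 km/12 min and
46 km/14 min).

`scenario_from_geography` selects the nearest facility of each role by
travel time (EMS base, PSC, and CSC by ground time from the scene; HEMS
base by air time), breaking ties by lexicographic name; the CSC mode
choice (ground) reflects that the ground drive defines how far the CSC
"really" is in a rural network. PSC-to-CSC legs are measured between the
selected facilities.

## Reachability maps and sensitivity

`reachability_map` evaluates the five strategies on a regular lat/lon
lattice of hypothetical scenes (no area weighting; this is planning
visualization, not demography). Cells are independent; each one re-derives
travel fields and re-runs the comparison. Grid cells inherit the name of
the geography's SCENE point, so override-table legs anchored to the scene
continue to apply — place a one-cell grid on the reference scene and the
case numbers reproduce exactly. Overrides anchored to a specific scene are,
of course, only physically meaningful near that scene; maps over large
areas should rely on the speed models.

`monte_carlo_sensitivity` propagates fixed / uniform / triangular marginals
through the model with `numpy.random.default_rng(seed)`; every endpoint
time is piecewise affine in each single parameter (at most one breakpoint,
from the parallel-dispatch `max()`), so means of deltas under symmetric
marginals away from the breakpoint equal their closed-form midpoint values
— a property the tests exploit as an oracle. Summaries (mean,
2.5/50/97.5 percentiles) are bit-identical per seed.

## Synthetic regions

`generate_geography` emulates the rural structure that makes the
strategy question interesting: facilities placed uniformly in a bounding
box, resampled (bounded retries, deterministic per seed) until, under the
default speed models, the ground time to the CSC exceeds 1.5× the ground
time to the PSC and the air time to the CSC is below its ground time.
Default counts (4 EMS bases, 1 HEMS base, 2 PSCs, 1 CSC) encode helicopter
sparsity. What the generator does **not** emulate: population density, road
topology, terrain, weather or night-flight availability, and helicopter
fleet contention — passing tests on synthetic regions therefore show
correctness of the timeline arithmetic and selection logic, not fidelity of
any specific real region.

`perturb_parameters` adds independent per-field noise and clips at zero;
clipping (rather than resampling) keeps the draw count deterministic but
slightly biases means for parameters near zero.

## Problem sizes and determinism

Every scenario evaluation is a handful of additions; the full test suite
(property tests with 100–1000 random parameter sets, a 100-region
constraint sweep, 10⁴ perturbation draws) runs in a few seconds. All
randomness flows through seeded `numpy` generators; identical seeds give
identical output at double precision.

## Known limitations

- Clinical outcomes are out of scope: the model ranks strategies by time to
  IVT/EVT only, with no outcome weighting.
- The dispatcher's aLVO recognition is taken as given; false positives and
  negatives of the dispatch query are not modeled.
- Leg times are static averages; time-of-day, congestion, and weather are
  not represented.
- A single patient and fully available resources are assumed — no queueing
  for helicopters or angiography suites.
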