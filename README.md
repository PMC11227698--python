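# stroketriage

Deterministic modeling of prehospital transport strategies for suspected
anterior large-vessel-occlusion (aLVO) stroke in rural regions.

When an aLVO stroke happens far from a comprehensive stroke center (CSC),
emergency services face a three-way choice:

- **drip-and-ship (DnS)** — ambulance to the nearest primary stroke center
  (PSC) for intravenous thrombolysis (IVT), then interhospital transfer to
  the CSC for endovascular thrombectomy (EVT);
- **mothership (MS)** — direct transport to the distant CSC (fast EVT,
  delayed IVT), by ambulance or by a helicopter that ground EMS must
  request after reaching the scene;
- **aLVO-guided dispatch** — the dispatcher recognizes a likely aLVO during
  the emergency call and activates ground EMS *and* the helicopter in
  parallel, so the aircraft is already on scene when the patient is ready.

`stroketriage` composes, for each strategy, the ordered milestone timeline
from symptom onset to CSC arrival as a cumulative sum of named segment
durations (minutes), with one non-additive rule for parallel dispatch:

```
depart_scene = max(ems_at_scene + on_scene, hems_at_scene)
time_to_ivt  = arrival_csc + door_to_needle          (direct-to-CSC)
             = arrival_psc + door_to_needle          (drip-and-ship)
time_to_evt  = time_to_ivt + needle_to_groin         (direct-to-CSC)
             = arrival_csc + door_to_groin           (drip-and-ship)
```

On top of the timeline model sit a great-circle routing layer (calibratable
speed models plus a measured-leg override table), reachability maps over a
grid of hypothetical scenes, Monte-Carlo parameter sensitivity, and a
seeded generator of synthetic rural regions. See `docs/methods.md` for the
full model description.

## Worked example

The built-in reference scenario is a rural case with the PSC 26 km away by
road and the CSC 90 km by road but only 46 km by air-line:

```bash
stroketriage compare --scenario examples/case_scenario.yaml \
    --out-table table.csv --out-json report.json
```

prints

```
fastest IVT: ALVO_DISPATCH
fastest EVT: ALVO_DISPATCH
```

and `table.csv` holds the per-strategy milestone table (minutes from
symptom onset; blank = not applicable):

```
Time from symptom onset to,aLVO-guided dispatch,MS air,MS ground,DnS air,DnS ground
Emergency call receipt,24,24,24,24,24
EMS dispatch,27,27,27,27,27
HEMS dispatch,29,,,,
Ambulance arrival at scene,37,37,37,37,37
Subsequent request of helicopter,,57,,,
Helicopter arrival at scene,41,74,,,
Start of ambulance transport,,,67,67,67
Start of helicopter transport,67,89,,,
Arrival at PSC,,,,87,87
Ambulance departure from PSC,,,,,147
Helicopter departure from PSC,,,,147,
Arrival at CSC,81,103,117,158,185
```

Reading the JSON report: with parallel dispatch the helicopter lands at
minute 41 — during the 30-minute on-scene interval — so the patient lifts
off at 67 and reaches the CSC at 81, receiving IVT at 111 and EVT at 171
minutes after onset. That is 6 minutes earlier to IVT than drip-and-ship
(117) and 22/47 minutes earlier to EVT than MS air (193) / DnS air (218).
Switching ground → air saves 14 minutes of CSC arrival in the mothership
strategies and 27 in drip-and-ship:

```python
>>> from stroketriage import *
>>> report = compare_strategies(generate_case_fixture()[0])
>>> {s.value: d for s, d in report.deltas_vs_alvo("evt").items()}
{'MS_AIR': 22.0, 'MS_GROUND': 36.0, 'DNS_AIR': 47.0, 'DNS_GROUND': 74.0}
>>> helicopter_transport_saving(report)
(14.0, 27.0)
```

Other commands: `stroketriage map` (reachability GeoJSON over a lat/lon
grid), `stroketriage sensitivity` (seeded Monte-Carlo sweeps), and
`stroketriage generate` (synthetic rural scenario configs, or the
reference case via `--case`).

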