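# Annotated scenario config: the reference rural aLVO stroke case.
#
# All values are minutes. Omitted parameters keep their defaults
# (which are exactly these values, so this file is also a schema demo).
# Run:  stroketriage compare --scenario examples/case_scenario.yaml \
#                            --out-table table.csv --out-json report.json
parameters:
  onset_to_call: 24              # symptom onset -> emergency call receipt
  call_to_ems_dispatch: 3        # dispatcher standard assessment
  ems_dispatch_to_hems_dispatch: 2  # aLVO-query continuation (parallel dispatch only)
  ems_base_to_scene: 10          # ambulance response travel
  hems_base_to_scene: 12         # helicopter response travel (parallel dispatch)
  on_scene: 30                   # EMS arrival -> ready to depart
  secondary_request_delay: 20    # EMS arrival -> helicopter request (MS air)
  hems_secondary_response: 17    # helicopter request -> at scene (MS air)
  handover_ems_hems: 15          # scene handover EMS -> HEMS (MS air)
  scene_to_csc_air: 14           # flight incl. take-off and landing (46 km air-line)
  scene_to_csc_ground: 50        # ambulance drive (90 km road)
  scene_to_psc_ground: 20        # ambulance drive (26 km road)
  psc_to_csc_ground: 38          # interhospital ambulance transfer
  psc_to_csc_air: 11             # interhospital flight
  door_to_needle: 30             # hospital arrival -> IVT start (PSC and CSC)
  needle_to_door: 30             # IVT start -> PSC departure (drip-and-ship)
  door_to_groin: 60              # CSC arrival -> puncture (drip-and-ship)
  needle_to_groin: 60            # IVT start -> puncture (direct-to-CSC)

# A `geography` block may replace the seven travel fields above:
#
# geography:
#   points:
#     - {name: scene, role: SCENE, lat: 48.10, lon: 8.20}
#     - {name: ambulance-base-1, role: EMS_BASE, lat: 48.15, lon: 8.25}
#     - {name: helicopter-base-2, role: HEMS_BASE, lat: 48.00, lon: 8.40}
#     - {name: psc, role: PSC, lat: 48.25, lon: 8.35}
#     - {name: csc, role: CSC, lat: 48.05, lon: 8.75}
#   speed_models:              # optional; defaults shown
#     GROUND: {cruise_speed_kmh: 90, circuity_factor: 1.4, overhead_min: 1}
#     AIR:    {cruise_speed_kmh: 220, circuity_factor: 1.0, overhead_min: 8}
#   travel_time_overrides:     # measured legs win verbatim over the model
#     - {from: scene, to: csc, mode: AIR, minutes: 14}
#
# Explicit `parameters` entries always win over geography-derived values.
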