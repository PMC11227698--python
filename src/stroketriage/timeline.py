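"""Milestone timelines for the five prehospital stroke transport strategies.

The model is deterministic interval arithmetic: every milestone is the
cumulative sum of named segment durations (minutes) along a strategy-specific
chain, measured from symptom onset.  The only non-additive step is the
parallel-dispatch rule of the aLVO-guided strategy, where scene departure is
the later of "EMS ready" (EMS arrival + on-scene time) and helicopter arrival.

Strategies
----------
ALVO_DISPATCH
    Dispatcher suspects an anterior large vessel occlusion (aLVO) during the
    emergency call and activates ground EMS and the helicopter (HEMS) in
    parallel; the helicopter flies the patient directly to the comprehensive
    stroke center (CSC).
MS_AIR / MS_GROUND
    Mothership: direct transport to the CSC, bypassing the primary stroke
    center (PSC).  In the air variant the helicopter is only requested after
    ground EMS reaches the scene (secondary request).
DNS_AIR / DNS_GROUND
    Drip-and-ship: ambulance to the nearest PSC for intravenous thrombolysis
    (IVT), then interhospital transfer to the CSC for endovascular
    thrombectomy (EVT), by helicopter or ambulance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields as dataclass_fields
from typing import Optional


class StrategyKind(enum.Enum):
    """The five transport strategies under comparison."""

    ALVO_DISPATCH = "ALVO_DISPATCH"
    MS_AIR = "MS_AIR"
    MS_GROUND = "MS_GROUND"
    DNS_AIR = "DNS_AIR"
    DNS_GROUND = "DNS_GROUND"


#: Fixed display / tie-break order (column order of the comparison table).
STRATEGY_ORDER = (
    StrategyKind.ALVO_DISPATCH,
    StrategyKind.MS_AIR,
    StrategyKind.MS_GROUND,
    StrategyKind.DNS_AIR,
    StrategyKind.DNS_GROUND,
)

# Milestone labels, verbatim as they appear in report rows.
LABEL_CALL = "Emergency call receipt"
LABEL_EMS_DISPATCH = "EMS dispatch"
LABEL_HEMS_DISPATCH = "HEMS dispatch"
LABEL_EMS_AT_SCENE = "Ambulance arrival at scene"
LABEL_HEMS_REQUEST = "Subsequent request of helicopter"
LABEL_HEMS_AT_SCENE = "Helicopter arrival at scene"
LABEL_DEPART_GROUND = "Start of ambulance transport"
LABEL_DEPART_AIR = "Start of helicopter transport"
LABEL_ARRIVAL_PSC = "Arrival at PSC"
LABEL_DEPART_PSC_GROUND = "Ambulance departure from PSC"
LABEL_DEPART_PSC_AIR = "Helicopter departure from PSC"
LABEL_ARRIVAL_CSC = "Arrival at CSC"

MILESTONE_LABELS = (
    LABEL_CALL,
    LABEL_EMS_DISPATCH,
    LABEL_HEMS_DISPATCH,
    LABEL_EMS_AT_SCENE,
    LABEL_HEMS_REQUEST,
    LABEL_HEMS_AT_SCENE,
    LABEL_DEPART_GROUND,
    LABEL_DEPART_AIR,
    LABEL_ARRIVAL_PSC,
    LABEL_DEPART_PSC_GROUND,
    LABEL_DEPART_PSC_AIR,
    LABEL_ARRIVAL_CSC,
)


@dataclass
class ScenarioParameters:
    """All named segment durations, in minutes.

    Defaults are the national-target / stroke-network values for care
    intervals together with the travel times of the reference rural case
    (near PSC at 26 km road distance, CSC at 90 km road / 46 km air-line
    distance).  Travel fields may instead be derived from geography via
    :func:`stroketriage.routing.scenario_from_geography`.
    """

    onset_to_call: Optional[float] = 24.0
    call_to_ems_dispatch: Optional[float] = 3.0
    ems_dispatch_to_hems_dispatch: Optional[float] = 2.0
    ems_base_to_scene: Optional[float] = 10.0
    hems_base_to_scene: Optional[float] = 12.0
    on_scene: Optional[float] = 30.0
    secondary_request_delay: Optional[float] = 20.0
    hems_secondary_response: Optional[float] = 17.0
    handover_ems_hems: Optional[float] = 15.0
    scene_to_csc_air: Optional[float] = 14.0
    scene_to_csc_ground: Optional[float] = 50.0
    scene_to_psc_ground: Optional[float] = 20.0
    psc_to_csc_ground: Optional[float] = 38.0
    psc_to_csc_air: Optional[float] = 11.0
    door_to_needle: Optional[float] = 30.0
    needle_to_door: Optional[float] = 30.0
    door_to_groin: Optional[float] = 60.0
    needle_to_groin: Optional[float] = 60.0

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclass_fields(cls))

    def replace(self, **changes: float) -> "ScenarioParameters":
        unknown = set(changes) - set(self.field_names())
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        data = {name: getattr(self, name) for name in self.field_names()}
        data.update(changes)
        return ScenarioParameters(**data)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.field_names()}


def validate_parameters(params: ScenarioParameters) -> list[str]:
    """Return a list of human-readable violations (empty iff valid).

    Checks presence (no ``None`` field) and non-negativity of every segment
    duration; each violation names the offending field.
    """
    violations = []
    for name in ScenarioParameters.field_names():
        value = getattr(params, name)
        if value is None:
            violations.append(f"{name}: missing (field must be present)")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            violations.append(f"{name}: not a number ({value!r})")
        elif value != value:  # NaN
            violations.append(f"{name}: not a number (NaN)")
        elif value < 0:
            violations.append(f"{name}: negative duration ({value} min); must be >= 0")
    return violations


def _require_valid(params: ScenarioParameters) -> None:
    violations = validate_parameters(params)
    if violations:
        raise ValueError("invalid scenario parameters: " + "; ".join(violations))


@dataclass
class Timeline:
    """Ordered milestones (minutes since symptom onset) for one strategy."""

    strategy: StrategyKind
    milestones: list[tuple[str, float]]
    arrival_psc: Optional[float]
    arrival_csc: float
    time_to_ivt: float
    time_to_evt: float
    total_on_scene: float

    def milestone(self, label: str) -> float:
        for lab, t in self.milestones:
            if lab == label:
                return t
        raise KeyError(f"timeline for {self.strategy.value} has no milestone {label!r}")

    def has_milestone(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.milestones)


def build_timeline(strategy: StrategyKind, params: ScenarioParameters) -> Timeline:
    """Compose the milestone chain for one strategy.

    Every milestone is its predecessor plus exactly one scenario segment,
    except scene departure under ``ALVO_DISPATCH`` which is
    ``max(ems_at_scene + on_scene, hems_at_scene)``: with parallel dispatch
    the helicopter either lands during on-scene care (handover absorbed into
    the on-scene interval) or, if it lands later, departure is its arrival
    because the patient is already packaged.
    """
    if not isinstance(strategy, StrategyKind):
        raise ValueError(f"unknown strategy: {strategy!r}")
    _require_valid(params)
    p = params

    call = p.onset_to_call
    ems_dispatch = call + p.call_to_ems_dispatch
    ems_at_scene = ems_dispatch + p.ems_base_to_scene
    milestones: list[tuple[str, float]] = [
        (LABEL_CALL, call),
        (LABEL_EMS_DISPATCH, ems_dispatch),
    ]
    arrival_psc: Optional[float] = None

    if strategy is StrategyKind.ALVO_DISPATCH:
        hems_dispatch = ems_dispatch + p.ems_dispatch_to_hems_dispatch
        hems_at_scene = hems_dispatch + p.hems_base_to_scene
        depart_scene = max(ems_at_scene + p.on_scene, hems_at_scene)
        arrival_csc = depart_scene + p.scene_to_csc_air
        milestones += [
            (LABEL_HEMS_DISPATCH, hems_dispatch),
            (LABEL_EMS_AT_SCENE, ems_at_scene),
            (LABEL_HEMS_AT_SCENE, hems_at_scene),
            (LABEL_DEPART_AIR, depart_scene),
            (LABEL_ARRIVAL_CSC, arrival_csc),
        ]
    elif strategy is StrategyKind.MS_AIR:
        request = ems_at_scene + p.secondary_request_delay
        hems_at_scene = request + p.hems_secondary_response
        depart_scene = hems_at_scene + p.handover_ems_hems
        arrival_csc = depart_scene + p.scene_to_csc_air
        milestones += [
            (LABEL_EMS_AT_SCENE, ems_at_scene),
            (LABEL_HEMS_REQUEST, request),
            (LABEL_HEMS_AT_SCENE, hems_at_scene),
            (LABEL_DEPART_AIR, depart_scene),
            (LABEL_ARRIVAL_CSC, arrival_csc),
        ]
    elif strategy is StrategyKind.MS_GROUND:
        depart_scene = ems_at_scene + p.on_scene
        arrival_csc = depart_scene + p.scene_to_csc_ground
        milestones += [
            (LABEL_EMS_AT_SCENE, ems_at_scene),
            (LABEL_DEPART_GROUND, depart_scene),
            (LABEL_ARRIVAL_CSC, arrival_csc),
        ]
    elif strategy in (StrategyKind.DNS_AIR, StrategyKind.DNS_GROUND):
        depart_scene = ems_at_scene + p.on_scene
        arrival_psc = depart_scene + p.scene_to_psc_ground
        depart_psc = arrival_psc + p.door_to_needle + p.needle_to_door
        if strategy is StrategyKind.DNS_AIR:
            transfer = p.psc_to_csc_air
            depart_label = LABEL_DEPART_PSC_AIR
        else:
            transfer = p.psc_to_csc_ground
            depart_label = LABEL_DEPART_PSC_GROUND
        arrival_csc = depart_psc + transfer
        milestones += [
            (LABEL_EMS_AT_SCENE, ems_at_scene),
            (LABEL_DEPART_GROUND, depart_scene),
            (LABEL_ARRIVAL_PSC, arrival_psc),
            (depart_label, depart_psc),
            (LABEL_ARRIVAL_CSC, arrival_csc),
        ]
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown strategy: {strategy!r}")

    total_on_scene = depart_scene - ems_at_scene
    ivt, evt = _treatment_times(strategy, arrival_psc, arrival_csc, p)
    return Timeline(
        strategy=strategy,
        milestones=milestones,
        arrival_psc=arrival_psc,
        arrival_csc=arrival_csc,
        time_to_ivt=ivt,
        time_to_evt=evt,
        total_on_scene=total_on_scene,
    )


def _treatment_times(
    strategy: StrategyKind,
    arrival_psc: Optional[float],
    arrival_csc: float,
    params: ScenarioParameters,
) -> tuple[float, float]:
    if strategy in (StrategyKind.DNS_AIR, StrategyKind.DNS_GROUND):
        if arrival_psc is None:
            raise ValueError("drip-and-ship timeline lacks a PSC arrival milestone")
        ivt = arrival_psc + params.door_to_needle
        evt = arrival_csc + params.door_to_groin
    else:
        ivt = arrival_csc + params.door_to_needle
        evt = ivt + params.needle_to_groin
    return ivt, evt


def time_to_treatments(
    timeline: Timeline, params: ScenarioParameters
) -> tuple[float, float]:
    """Derive (time-to-IVT, time-to-EVT) in minutes from onset.

    Direct-to-CSC strategies (aLVO-guided, mothership) receive IVT on CSC
    arrival (door-to-needle) and EVT after the needle-to-groin interval.
    Drip-and-ship receives IVT at the PSC and EVT on CSC arrival plus
    door-to-groin.
    """
    _require_valid(params)
    return _treatment_times(
        timeline.strategy, timeline.arrival_psc, timeline.arrival_csc, params
    )
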