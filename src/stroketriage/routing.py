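"""Great-circle travel-time models for ground and helicopter EMS.

Real deployments take travel times from a road-network routing service; here
segment times either come verbatim from a measured override table or from a
simple calibratable speed model,

    time_min = 60 * circuity_factor * haversine_km / cruise_speed_kmh
               + overhead_min

where the circuity factor converts air-line (great-circle) distance to road
distance (fixed at 1 for flight) and the per-leg overhead covers crew
mobilization (ground) or take-off plus landing (air).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


class PointRole(enum.Enum):
    SCENE = "SCENE"
    EMS_BASE = "EMS_BASE"
    HEMS_BASE = "HEMS_BASE"
    PSC = "PSC"
    CSC = "CSC"


class TravelMode(enum.Enum):
    GROUND = "GROUND"
    AIR = "AIR"


@dataclass(frozen=True)
class GeoPoint:
    """A named facility or scene location in WGS84 decimal degrees."""

    lat: float
    lon: float
    role: PointRole
    name: str

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range for {self.name!r}: {self.lat}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range for {self.name!r}: {self.lon}")


@dataclass(frozen=True)
class SpeedModel:
    """Linear time-vs-distance model for one travel mode."""

    mode: TravelMode
    cruise_speed_kmh: float
    circuity_factor: float = 1.0
    overhead_min: float = 0.0

    def __post_init__(self) -> None:
        if self.cruise_speed_kmh <= 0:
            raise ValueError(f"cruise_speed_kmh must be > 0, got {self.cruise_speed_kmh}")
        if self.circuity_factor < 1.0:
            raise ValueError(f"circuity_factor must be >= 1, got {self.circuity_factor}")
        if self.overhead_min < 0:
            raise ValueError(f"overhead_min must be >= 0, got {self.overhead_min}")

    @property
    def minutes_per_km(self) -> float:
        """Slope of the time-vs-air-line-distance line."""
        return 60.0 * self.circuity_factor / self.cruise_speed_kmh


#: Defaults for synthetic regions; config-overridable, roughly consistent
#: with rural lights-and-siren ambulance runs and HEMS flight profiles.
DEFAULT_GROUND_MODEL = SpeedModel(
    TravelMode.GROUND, cruise_speed_kmh=90.0, circuity_factor=1.4, overhead_min=1.0
)
DEFAULT_AIR_MODEL = SpeedModel(
    TravelMode.AIR, cruise_speed_kmh=220.0, circuity_factor=1.0, overhead_min=8.0
)


@dataclass
class TravelTimeTable:
    """Measured (origin, destination, mode) -> minutes overrides.

    Entries win verbatim over model predictions; lookups are exact-match on
    the name triple, tried in both directions.
    """

    entries: dict[tuple[str, str, TravelMode], float] = field(default_factory=dict)

    def set(self, origin: str, destination: str, mode: TravelMode, minutes: float) -> None:
        if minutes < 0:
            raise ValueError(
                f"travel time override {origin!r}->{destination!r} is negative: {minutes}"
            )
        self.entries[(origin, destination, mode)] = float(minutes)

    def get(self, origin: str, destination: str, mode: TravelMode) -> Optional[float]:
        hit = self.entries.get((origin, destination, mode))
        if hit is None:
            hit = self.entries.get((destination, origin, mode))
        return hit


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km (spherical Earth, R = 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def travel_time_min(a: GeoPoint, b: GeoPoint, model: SpeedModel) -> float:
    """Predicted leg time in minutes under ``model``."""
    return model.minutes_per_km * haversine_km(a, b) + model.overhead_min


def calibrate_speed_model(
    observations: Sequence[tuple[float, float]],
    mode: TravelMode,
    circuity_factor: float = 1.0,
) -> SpeedModel:
    """Least-squares fit of a speed model to (distance_km, observed_min) pairs.

    Fits slope (min/km) and intercept (overhead) by ordinary least squares;
    a negative intercept is clipped to zero and the slope refit through the
    origin.  The circuity factor is not identifiable from times alone and is
    taken as given (1 for air); the cruise speed absorbs the slope.
    """
    obs = [(float(d), float(t)) for d, t in observations]
    distances = {d for d, _ in obs}
    if len(distances) < 2:
        raise ValueError(
            f"calibration needs >= 2 observations with distinct distances, got {len(distances)}"
        )
    d = np.array([x for x, _ in obs])
    t = np.array([y for _, y in obs])
    slope, intercept = np.polyfit(d, t, 1)
    if intercept < 0.0:
        intercept = 0.0
        slope = float(np.dot(d, t) / np.dot(d, d))
    if slope <= 0:
        raise ValueError(f"calibrated slope is non-positive ({slope:.4g} min/km)")
    cruise = 60.0 * circuity_factor / float(slope)
    return SpeedModel(
        mode=mode,
        cruise_speed_kmh=cruise,
        circuity_factor=circuity_factor,
        overhead_min=float(intercept),
    )


def _leg_time(
    a: GeoPoint,
    b: GeoPoint,
    mode: TravelMode,
    models: Mapping[TravelMode, SpeedModel],
    overrides: Optional[TravelTimeTable],
) -> float:
    if overrides is not None:
        hit = overrides.get(a.name, b.name, mode)
        if hit is not None:
            return hit
    return travel_time_min(a, b, models[mode])


def _nearest(
    origin: GeoPoint,
    candidates: Sequence[GeoPoint],
    mode: TravelMode,
    models: Mapping[TravelMode, SpeedModel],
    overrides: Optional[TravelTimeTable],
) -> tuple[GeoPoint, float]:
    # deterministic: minimize (time, name)
    best = min(
        candidates,
        key=lambda c: (_leg_time(origin, c, mode, models, overrides), c.name),
    )
    return best, _leg_time(origin, best, mode, models, overrides)


def scenario_from_geography(
    points: Iterable[GeoPoint],
    models: Optional[Mapping[TravelMode, SpeedModel]] = None,
    overrides: Optional[TravelTimeTable] = None,
) -> dict[str, float]:
    """Derive the seven scenario travel fields from a facility layout.

    Selects the nearest facility of each role by travel time (ties broken by
    lexicographic name): EMS base and PSC by ground, HEMS base by air, the
    CSC by ground time from the scene.  PSC-to-CSC legs are measured from the
    selected PSC to the selected CSC.  Any leg present in ``overrides`` is
    used verbatim, both for selection and in the returned times.
    """
    if models is None:
        models = {
            TravelMode.GROUND: DEFAULT_GROUND_MODEL,
            TravelMode.AIR: DEFAULT_AIR_MODEL,
        }
    pts = list(points)
    by_role: dict[PointRole, list[GeoPoint]] = {role: [] for role in PointRole}
    for p in pts:
        by_role[p.role].append(p)
    if len(by_role[PointRole.SCENE]) != 1:
        raise ValueError(
            f"geography must contain exactly one SCENE, got {len(by_role[PointRole.SCENE])}"
        )
    for role in (PointRole.EMS_BASE, PointRole.HEMS_BASE, PointRole.PSC, PointRole.CSC):
        if not by_role[role]:
            raise ValueError(f"geography is missing a point with role {role.value}")

    scene = by_role[PointRole.SCENE][0]
    _, ems_t = _nearest(scene, by_role[PointRole.EMS_BASE], TravelMode.GROUND, models, overrides)
    _, hems_t = _nearest(scene, by_role[PointRole.HEMS_BASE], TravelMode.AIR, models, overrides)
    psc, psc_t = _nearest(scene, by_role[PointRole.PSC], TravelMode.GROUND, models, overrides)
    csc, csc_ground_t = _nearest(scene, by_role[PointRole.CSC], TravelMode.GROUND, models, overrides)

    return {
        "ems_base_to_scene": ems_t,
        "hems_base_to_scene": hems_t,
        "scene_to_psc_ground": psc_t,
        "scene_to_csc_ground": csc_ground_t,
        "scene_to_csc_air": _leg_time(scene, csc, TravelMode.AIR, models, overrides),
        "psc_to_csc_ground": _leg_time(psc, csc, TravelMode.GROUND, models, overrides),
        "psc_to_csc_air": _leg_time(psc, csc, TravelMode.AIR, models, overrides),
    }


def points_to_geojson(points: Iterable[GeoPoint]) -> dict:
    """GeoJSON FeatureCollection of the facility layout."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {"name": p.name, "role": p.role.value},
            }
            for p in points
        ],
    }
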