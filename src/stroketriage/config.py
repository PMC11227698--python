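"""Scenario configuration: YAML/JSON parsing, validation, serialization.

A scenario file has two top-level blocks:

``parameters``
    Any subset of the named segment durations (minutes).  Unlisted fields
    keep their defaults.
``geography`` (optional)
    ``points`` (name/role/lat/lon), optional ``speed_models`` per mode, and
    optional ``travel_time_overrides`` carrying measured leg times.  When a
    geography is present the seven travel fields are derived from it; an
    explicit ``parameters`` entry always wins over a derived value.

Unknown keys anywhere are an error naming the key - silent typos in minute
values are the classic way to get a plausible-looking wrong timeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .routing import (
    DEFAULT_AIR_MODEL,
    DEFAULT_GROUND_MODEL,
    GeoPoint,
    PointRole,
    SpeedModel,
    TravelMode,
    TravelTimeTable,
    scenario_from_geography,
)
from .timeline import ScenarioParameters, validate_parameters

_TRAVEL_FIELDS = (
    "ems_base_to_scene",
    "hems_base_to_scene",
    "scene_to_psc_ground",
    "scene_to_csc_ground",
    "scene_to_csc_air",
    "psc_to_csc_ground",
    "psc_to_csc_air",
)


class ConfigError(ValueError):
    """Raised for malformed scenario files; message names the offending key."""


@dataclass
class Geography:
    points: list[GeoPoint]
    models: dict[TravelMode, SpeedModel] = field(
        default_factory=lambda: {
            TravelMode.GROUND: DEFAULT_GROUND_MODEL,
            TravelMode.AIR: DEFAULT_AIR_MODEL,
        }
    )
    overrides: Optional[TravelTimeTable] = None


@dataclass
class Scenario:
    params: ScenarioParameters
    geography: Optional[Geography] = None


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(map(repr, unknown))}")


def _parse_geography(block: dict) -> Geography:
    _reject_unknown(block, {"points", "speed_models", "travel_time_overrides"}, "geography")
    raw_points = block.get("points", [])
    if not raw_points:
        raise ConfigError("geography block has no 'points'")
    points = []
    for i, entry in enumerate(raw_points):
        _reject_unknown(entry, {"name", "role", "lat", "lon"}, f"geography.points[{i}]")
        try:
            role = PointRole(entry["role"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"geography.points[{i}]: bad or missing role: {exc}") from exc
        points.append(
            GeoPoint(float(entry["lat"]), float(entry["lon"]), role, str(entry["name"]))
        )

    models = {TravelMode.GROUND: DEFAULT_GROUND_MODEL, TravelMode.AIR: DEFAULT_AIR_MODEL}
    for mode_name, spec in (block.get("speed_models") or {}).items():
        try:
            mode = TravelMode(mode_name)
        except ValueError as exc:
            raise ConfigError(f"speed_models: unknown mode {mode_name!r}") from exc
        _reject_unknown(
            spec,
            {"cruise_speed_kmh", "circuity_factor", "overhead_min"},
            f"speed_models.{mode_name}",
        )
        defaults = models[mode]
        models[mode] = SpeedModel(
            mode=mode,
            cruise_speed_kmh=float(spec.get("cruise_speed_kmh", defaults.cruise_speed_kmh)),
            circuity_factor=float(spec.get("circuity_factor", defaults.circuity_factor)),
            overhead_min=float(spec.get("overhead_min", defaults.overhead_min)),
        )

    overrides = None
    raw_overrides = block.get("travel_time_overrides")
    if raw_overrides:
        overrides = TravelTimeTable()
        for i, entry in enumerate(raw_overrides):
            _reject_unknown(
                entry, {"from", "to", "mode", "minutes"}, f"travel_time_overrides[{i}]"
            )
            try:
                mode = TravelMode(entry["mode"])
            except (KeyError, ValueError) as exc:
                raise ConfigError(
                    f"travel_time_overrides[{i}]: bad or missing mode: {exc}"
                ) from exc
            overrides.set(
                str(entry["from"]), str(entry["to"]), mode, float(entry["minutes"])
            )
    return Geography(points=points, models=models, overrides=overrides)


def scenario_from_dict(doc: dict) -> Scenario:
    """Build a validated scenario from an already-parsed mapping."""
    if not isinstance(doc, dict):
        raise ConfigError(f"scenario document must be a mapping, got {type(doc).__name__}")
    _reject_unknown(doc, {"parameters", "geography"}, "scenario")

    raw_params = doc.get("parameters") or {}
    known = set(ScenarioParameters.field_names())
    _reject_unknown(raw_params, known, "parameters")

    geography = None
    params = ScenarioParameters()
    if "geography" in doc and doc["geography"] is not None:
        geography = _parse_geography(doc["geography"])
        travel = scenario_from_geography(
            geography.points, geography.models, geography.overrides
        )
        params = params.replace(**travel)
    # explicit parameters win over geography-derived travel fields
    params = params.replace(**{k: float(v) for k, v in raw_params.items()})

    violations = validate_parameters(params)
    if violations:
        raise ConfigError("invalid parameters: " + "; ".join(violations))
    return Scenario(params=params, geography=geography)


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"scenario file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return scenario_from_dict(doc)


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Serialize a scenario to a plain mapping (round-trips via load)."""
    doc: dict[str, Any] = {"parameters": scenario.params.as_dict()}
    geo = scenario.geography
    if geo is not None:
        block: dict[str, Any] = {
            "points": [
                {"name": p.name, "role": p.role.value, "lat": p.lat, "lon": p.lon}
                for p in geo.points
            ],
            "speed_models": {
                mode.value: {
                    "cruise_speed_kmh": m.cruise_speed_kmh,
                    "circuity_factor": m.circuity_factor,
                    "overhead_min": m.overhead_min,
                }
                for mode, m in geo.models.items()
            },
        }
        if geo.overrides is not None:
            block["travel_time_overrides"] = [
                {"from": o, "to": d, "mode": mode.value, "minutes": minutes}
                for (o, d, mode), minutes in sorted(
                    geo.overrides.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
                )
            ]
        doc["geography"] = block
    return doc


def save_scenario(scenario: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario as YAML (or JSON if the extension says so)."""
    path = Path(path)
    doc = scenario_to_dict(scenario)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
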