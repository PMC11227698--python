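"""Seeded synthetic rural scenarios: geographies and parameter sets.

The generator emulates the geographic structure in which the transport-
strategy question is interesting at all: a rural scene with a nearby primary
stroke center, a comprehensive stroke center much farther by road than the
PSC but closer by air-line than by road (so helicopter transport pays off),
and helicopter bases sparser than ambulance bases.  Facilities are placed
uniformly in a bounding box and the layout is resampled until the structural
constraints hold under the default speed models; there is no population-
density model - rurality is a constraint, not a density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .routing import (
    DEFAULT_AIR_MODEL,
    DEFAULT_GROUND_MODEL,
    GeoPoint,
    PointRole,
    TravelMode,
    TravelTimeTable,
    scenario_from_geography,
)
from .timeline import ScenarioParameters, validate_parameters


@dataclass
class RegionSpec:
    """Recipe for one synthetic rural region.

    Default counts reflect the rural sparsity pattern: several ambulance
    bases, a single helicopter base, a couple of PSCs, one distant CSC.
    """

    south: float = 47.5
    west: float = 7.5
    north: float = 48.5
    east: float = 8.8
    n_ems_bases: int = 4
    n_hems_bases: int = 1
    n_psc: int = 2
    n_csc: int = 1
    #: scene->CSC ground time must exceed scene->PSC ground time by this factor
    min_csc_psc_ratio: float = 1.5
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.north <= self.south or self.east <= self.west:
            raise ValueError("bounding box is degenerate")
        for name in ("n_ems_bases", "n_hems_bases", "n_psc", "n_csc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _draw_points(spec: RegionSpec, rng: np.random.Generator) -> list[GeoPoint]:
    def uniform_point(role: PointRole, name: str) -> GeoPoint:
        lat = float(rng.uniform(spec.south, spec.north))
        lon = float(rng.uniform(spec.west, spec.east))
        return GeoPoint(lat, lon, role, name)

    points = [uniform_point(PointRole.SCENE, "scene")]
    points += [
        uniform_point(PointRole.EMS_BASE, f"ems-{i + 1}") for i in range(spec.n_ems_bases)
    ]
    points += [
        uniform_point(PointRole.HEMS_BASE, f"hems-{i + 1}") for i in range(spec.n_hems_bases)
    ]
    points += [uniform_point(PointRole.PSC, f"psc-{i + 1}") for i in range(spec.n_psc)]
    points += [uniform_point(PointRole.CSC, f"csc-{i + 1}") for i in range(spec.n_csc)]
    return points


def check_rural_constraints(spec: RegionSpec, travel: Mapping[str, float]) -> bool:
    """True iff derived travel fields show the rural structure."""
    return (
        travel["scene_to_csc_ground"]
        >= spec.min_csc_psc_ratio * travel["scene_to_psc_ground"]
        and travel["scene_to_csc_air"] < travel["scene_to_csc_ground"]
    )


def generate_geography(spec: RegionSpec) -> list[GeoPoint]:
    """Draw a facility layout satisfying the rural structural constraints.

    Deterministic per ``spec.seed``.  Raises if the constraints cannot be
    met within ``spec.max_retries`` resamples (e.g. an over-tight ratio in a
    tiny box), reporting the number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    models = {TravelMode.GROUND: DEFAULT_GROUND_MODEL, TravelMode.AIR: DEFAULT_AIR_MODEL}
    for attempt in range(spec.max_retries):
        points = _draw_points(spec, rng)
        travel = scenario_from_geography(points, models)
        if check_rural_constraints(spec, travel):
            return points
    raise RuntimeError(
        f"could not satisfy rural constraints in {spec.max_retries} attempts "
        f"(box {spec.south},{spec.west},{spec.north},{spec.east}, "
        f"ratio >= {spec.min_csc_psc_ratio}); relax the ratio or enlarge the box"
    )


# ---------------------------------------------------------------------------
# The reference case fixture
# ---------------------------------------------------------------------------

#: Clock time of symptom onset in the reference case, for report rendering.
CASE_ONSET_CLOCK = "17:15"

#: Printed case distances (km): PSC 26 by road, CSC 90 by road / 46 air-line,
#: helicopter base 26 by air.
CASE_DISTANCES_KM = {
    "scene_to_psc_road": 26.0,
    "scene_to_csc_road": 90.0,
    "scene_to_csc_air": 46.0,
    "hems_base_to_scene_air": 26.0,
}


def generate_case_fixture() -> tuple[ScenarioParameters, TravelTimeTable, dict[str, str]]:
    """The reference rural case: parameters, measured legs, facility labels.

    Returns the canonical scenario (all segment durations as observed or set
    to national-target defaults), a travel-time override table carrying the
    measured legs, and the label mapping used by those overrides.
    """
    params = ScenarioParameters()  # defaults ARE the case values
    labels = {
        "scene": "scene",
        "ems_base": "ambulance-base-1",
        "hems_base": "helicopter-base-2",
        "psc": "psc",
        "csc": "csc",
    }
    table = TravelTimeTable()
    table.set(labels["ems_base"], labels["scene"], TravelMode.GROUND, params.ems_base_to_scene)
    table.set(labels["hems_base"], labels["scene"], TravelMode.AIR, params.hems_base_to_scene)
    table.set(labels["scene"], labels["csc"], TravelMode.AIR, params.scene_to_csc_air)
    table.set(labels["scene"], labels["csc"], TravelMode.GROUND, params.scene_to_csc_ground)
    table.set(labels["scene"], labels["psc"], TravelMode.GROUND, params.scene_to_psc_ground)
    table.set(labels["psc"], labels["csc"], TravelMode.GROUND, params.psc_to_csc_ground)
    table.set(labels["psc"], labels["csc"], TravelMode.AIR, params.psc_to_csc_air)
    return params, table, labels


# ---------------------------------------------------------------------------
# Parameter perturbation
# ---------------------------------------------------------------------------


def perturb_parameters(
    params: ScenarioParameters,
    noise_spec: Mapping[str, Sequence],
    seed: int,
) -> ScenarioParameters:
    """Additive noise on named parameters, clipped at zero.

    ``noise_spec`` maps field name -> ("uniform", lo, hi) or
    ("normal", mu, sigma); draws are independent and added to the current
    value.  Clipping at zero (rather than resampling) keeps the draw count
    deterministic but slightly biases means for values near zero.
    """
    rng = np.random.default_rng(seed)
    known = set(ScenarioParameters.field_names())
    changes = {}
    for name in sorted(noise_spec):  # sorted: draw order independent of dict order
        if name not in known:
            raise ValueError(f"unknown parameter in noise spec: {name!r}")
        dist = noise_spec[name]
        kind = dist[0]
        if kind == "uniform":
            lo, hi = float(dist[1]), float(dist[2])
            if lo > hi:
                raise ValueError(f"{name}: uniform bounds reversed (lo={lo} > hi={hi})")
            noise = float(rng.uniform(lo, hi)) if hi > lo else lo
        elif kind == "normal":
            mu, sigma = float(dist[1]), float(dist[2])
            if sigma < 0:
                raise ValueError(f"{name}: negative sigma {sigma}")
            noise = float(rng.normal(mu, sigma)) if sigma > 0 else mu
        else:
            raise ValueError(f"{name}: unknown noise kind {kind!r}")
        changes[name] = max(0.0, getattr(params, name) + noise)
    perturbed = params.replace(**changes)
    assert not validate_parameters(perturbed)
    return perturbed
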