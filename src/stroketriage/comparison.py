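"""Strategy comparison, reachability maps, and sensitivity sweeps.

``compare_strategies`` is the machine-readable comparison table: all five
timelines, their treatment times, and pairwise deltas for both endpoints.
The delta sign convention is "minutes earlier with aLVO-guided dispatch":
delta(other) = time(other) - time(ALVO_DISPATCH), positive when the
parallel-dispatch strategy is faster.

``reachability_map`` generalizes the single case to a grid of hypothetical
emergency scenes: each cell re-derives travel fields from the geography and
records the winning strategy per treatment endpoint.

``monte_carlo_sensitivity`` propagates parameter uncertainty (fixed /
uniform / triangular marginals) through the deterministic timeline model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .routing import (
    GeoPoint,
    PointRole,
    SpeedModel,
    TravelMode,
    TravelTimeTable,
    scenario_from_geography,
)
from .timeline import (
    STRATEGY_ORDER,
    ScenarioParameters,
    StrategyKind,
    Timeline,
    build_timeline,
)


@dataclass
class ComparisonReport:
    """Per-strategy timelines, treatment times, and pairwise deltas."""

    timelines: dict[StrategyKind, Timeline]

    @property
    def time_to_ivt(self) -> dict[StrategyKind, float]:
        return {s: t.time_to_ivt for s, t in self.timelines.items()}

    @property
    def time_to_evt(self) -> dict[StrategyKind, float]:
        return {s: t.time_to_evt for s, t in self.timelines.items()}

    @property
    def total_on_scene(self) -> dict[StrategyKind, float]:
        return {s: t.total_on_scene for s, t in self.timelines.items()}

    def delta(self, a: StrategyKind, b: StrategyKind, endpoint: str = "ivt") -> float:
        """time(a) - time(b) for the given endpoint ('ivt' or 'evt')."""
        times = self._endpoint(endpoint)
        return times[a] - times[b]

    def deltas_vs_alvo(self, endpoint: str = "ivt") -> dict[StrategyKind, float]:
        """Minutes by which each strategy trails aLVO-guided dispatch."""
        return {
            s: self.delta(s, StrategyKind.ALVO_DISPATCH, endpoint)
            for s in STRATEGY_ORDER
            if s is not StrategyKind.ALVO_DISPATCH
        }

    def fastest(self, endpoint: str = "ivt") -> StrategyKind:
        """Winning strategy; ties resolved by the fixed strategy order."""
        times = self._endpoint(endpoint)
        return min(STRATEGY_ORDER, key=lambda s: (times[s], STRATEGY_ORDER.index(s)))

    def _endpoint(self, endpoint: str) -> dict[StrategyKind, float]:
        if endpoint == "ivt":
            return self.time_to_ivt
        if endpoint == "evt":
            return self.time_to_evt
        raise ValueError(f"unknown endpoint {endpoint!r}; expected 'ivt' or 'evt'")


def compare_strategies(params: ScenarioParameters) -> ComparisonReport:
    """Run all five strategies on one scenario."""
    return ComparisonReport(
        timelines={s: build_timeline(s, params) for s in STRATEGY_ORDER}
    )


def helicopter_transport_saving(report: ComparisonReport) -> tuple[float, float]:
    """CSC-arrival minutes saved by switching ground -> air transport.

    Returns ``(ms_saving, dns_saving)``: the mothership saving compares
    direct-transport variants, the drip-and-ship saving the interhospital
    transfer variants.
    """
    tl = report.timelines
    ms = tl[StrategyKind.MS_GROUND].arrival_csc - tl[StrategyKind.MS_AIR].arrival_csc
    dns = tl[StrategyKind.DNS_GROUND].arrival_csc - tl[StrategyKind.DNS_AIR].arrival_csc
    return ms, dns


@dataclass
class ReachabilityCell:
    """One grid location with per-strategy endpoint times and winners."""

    center: GeoPoint
    time_to_ivt: dict[StrategyKind, float]
    time_to_evt: dict[StrategyKind, float]
    winner_ivt: StrategyKind
    winner_evt: StrategyKind


def reachability_map(
    points: Iterable[GeoPoint],
    bbox: tuple[float, float, float, float],
    step_deg: float,
    params_template: ScenarioParameters,
    models: Optional[Mapping[TravelMode, SpeedModel]] = None,
    overrides: Optional[TravelTimeTable] = None,
) -> list[ReachabilityCell]:
    """Evaluate all strategies on a lat/lon lattice of hypothetical scenes.

    ``bbox`` is (south, west, north, east); cell centers start at the
    south-west corner and advance by ``step_deg``.  Facility points keep
    their roles; any SCENE point in ``points`` is replaced by the cell
    center but keeps its name, so override-table legs anchored to the scene
    continue to apply.  Cells are independent: each is a fresh travel-field
    derivation plus a full strategy comparison.
    """
    if step_deg <= 0:
        raise ValueError(f"grid step must be > 0, got {step_deg}")
    south, west, north, east = bbox
    all_points = list(points)
    scene_name = next(
        (p.name for p in all_points if p.role is PointRole.SCENE), "cell"
    )
    facilities = [p for p in all_points if p.role is not PointRole.SCENE]
    lats = np.arange(south, north + 1e-12, step_deg)
    lons = np.arange(west, east + 1e-12, step_deg)
    if lats.size == 0 or lons.size == 0:
        raise ValueError(f"empty grid for bbox {bbox} at step {step_deg}")

    cells = []
    for lat in lats:
        for lon in lons:
            center = GeoPoint(float(lat), float(lon), PointRole.SCENE, scene_name)
            cells.append(
                evaluate_cell(center, facilities, params_template, models, overrides)
            )
    return cells


def evaluate_cell(
    center: GeoPoint,
    facilities: Sequence[GeoPoint],
    params_template: ScenarioParameters,
    models: Optional[Mapping[TravelMode, SpeedModel]] = None,
    overrides: Optional[TravelTimeTable] = None,
) -> ReachabilityCell:
    """Run the five-strategy comparison with ``center`` as the scene."""
    travel = scenario_from_geography([center, *facilities], models, overrides)
    report = compare_strategies(params_template.replace(**travel))
    return ReachabilityCell(
        center=center,
        time_to_ivt=report.time_to_ivt,
        time_to_evt=report.time_to_evt,
        winner_ivt=report.fastest("ivt"),
        winner_evt=report.fastest("evt"),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo sensitivity
# ---------------------------------------------------------------------------

Distribution = tuple  # ("fixed", v) | ("uniform", lo, hi) | ("triangular", lo, mode, hi)


def _validate_distribution(name: str, dist: Sequence) -> None:
    kind = dist[0]
    if kind == "fixed":
        if len(dist) != 2:
            raise ValueError(f"{name}: fixed takes one value, got {dist!r}")
    elif kind == "uniform":
        if len(dist) != 3:
            raise ValueError(f"{name}: uniform takes (lo, hi), got {dist!r}")
        lo, hi = dist[1], dist[2]
        if lo > hi:
            raise ValueError(f"{name}: uniform bounds reversed (lo={lo} > hi={hi})")
    elif kind == "triangular":
        if len(dist) != 4:
            raise ValueError(f"{name}: triangular takes (lo, mode, hi), got {dist!r}")
        lo, mode, hi = dist[1], dist[2], dist[3]
        if not (lo <= mode <= hi):
            raise ValueError(
                f"{name}: triangular needs lo <= mode <= hi, got ({lo}, {mode}, {hi})"
            )
    else:
        raise ValueError(f"{name}: unknown distribution kind {kind!r}")


def _draw(dist: Sequence, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        lo, hi = dist[1], dist[2]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    # triangular; degenerate widths handled by numpy
    lo, mode, hi = dist[1], dist[2], dist[3]
    return float(lo) if hi == lo else float(rng.triangular(lo, mode, hi))


def monte_carlo_sensitivity(
    param_distributions: Mapping[str, Sequence],
    n: int,
    seed: int,
    base_params: Optional[ScenarioParameters] = None,
) -> dict[str, dict[str, float]]:
    """Distribution summaries of endpoint deltas under parameter uncertainty.

    Each listed parameter is drawn independently per replicate; unlisted
    parameters keep their ``base_params`` value.  Returns, per delta key
    (``"<endpoint>_delta_vs_alvo:<STRATEGY>"``), the mean and the
    2.5/50/97.5 percentiles over ``n`` replicates.  Re-running with the same
    seed is bit-identical.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if base_params is None:
        base_params = ScenarioParameters()
    known = set(ScenarioParameters.field_names())
    for name, dist in param_distributions.items():
        if name not in known:
            raise ValueError(f"unknown parameter in distribution spec: {name!r}")
        _validate_distribution(name, dist)

    rng = np.random.default_rng(seed)
    others = [s for s in STRATEGY_ORDER if s is not StrategyKind.ALVO_DISPATCH]
    draws: dict[str, list[float]] = {
        f"{ep}_delta_vs_alvo:{s.value}": [] for ep in ("ivt", "evt") for s in others
    }
    for _ in range(n):
        sampled = {k: _draw(d, rng) for k, d in param_distributions.items()}
        report = compare_strategies(base_params.replace(**sampled))
        for ep in ("ivt", "evt"):
            for s, delta in report.deltas_vs_alvo(ep).items():
                draws[f"{ep}_delta_vs_alvo:{s.value}"].append(delta)

    summaries = {}
    for key, values in draws.items():
        arr = np.asarray(values)
        q = np.percentile(arr, [2.5, 50.0, 97.5])
        summaries[key] = {
            "mean": float(arr.mean()),
            "p2.5": float(q[0]),
            "p50": float(q[1]),
            "p97.5": float(q[2]),
        }
    return summaries


def cells_to_geojson(cells: Sequence[ReachabilityCell]) -> dict:
    """GeoJSON FeatureCollection of reachability cells."""
    features = []
    for c in cells:
        props: dict = {
            "winner_ivt": c.winner_ivt.value,
            "winner_evt": c.winner_evt.value,
        }
        for s in STRATEGY_ORDER:
            props[f"ivt_{s.value}"] = c.time_to_ivt[s]
            props[f"evt_{s.value}"] = c.time_to_evt[s]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [c.center.lon, c.center.lat],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
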