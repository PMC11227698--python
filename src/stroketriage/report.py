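"""Report writers: comparison table CSV, JSON document, GeoJSON maps.

Minutes render as integers by default (half-up), matching the convention of
operational stroke-network reporting; pass a ``precision`` for decimals in
synthetic work.  Writers are pure functions of the report, so re-running on
the same report is byte-identical.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

from .comparison import (
    ComparisonReport,
    ReachabilityCell,
    cells_to_geojson,
    helicopter_transport_saving,
)
from .timeline import MILESTONE_LABELS, STRATEGY_ORDER, StrategyKind

STRATEGY_DISPLAY = {
    StrategyKind.ALVO_DISPATCH: "aLVO-guided dispatch",
    StrategyKind.MS_AIR: "MS air",
    StrategyKind.MS_GROUND: "MS ground",
    StrategyKind.DNS_AIR: "DnS air",
    StrategyKind.DNS_GROUND: "DnS ground",
}


def format_minutes(value: float, precision: int = 0) -> str:
    """Render minutes with half-up rounding at ``precision`` decimals."""
    scale = 10**precision
    rounded = math.floor(value * scale + 0.5) / scale
    if precision == 0:
        return str(int(rounded))
    return f"{rounded:.{precision}f}"


def comparison_table_rows(
    report: ComparisonReport, precision: int = 0
) -> list[list[str]]:
    """Table rows: milestones x strategies, blank where not applicable."""
    rows = [["Time from symptom onset to", *(STRATEGY_DISPLAY[s] for s in STRATEGY_ORDER)]]
    for label in MILESTONE_LABELS:
        cells = []
        for s in STRATEGY_ORDER:
            tl = report.timelines[s]
            cells.append(
                format_minutes(tl.milestone(label), precision)
                if tl.has_milestone(label)
                else ""
            )
        if any(cells):
            rows.append([label, *cells])
    return rows


def write_comparison_csv(
    report: ComparisonReport, path: Union[str, Path], precision: int = 0
) -> None:
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(comparison_table_rows(report, precision))


def write_timelines_csv(
    report: ComparisonReport, path: Union[str, Path], precision: int = 0
) -> None:
    """Long format: strategy,label,minutes_from_onset - one row per milestone."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["strategy", "label", "minutes_from_onset"])
        for s in STRATEGY_ORDER:
            for label, t in report.timelines[s].milestones:
                writer.writerow([s.value, label, format_minutes(t, precision)])


def report_to_dict(report: ComparisonReport, precision: Optional[int] = None) -> dict:
    """JSON-ready document: timelines, treatment times, deltas, winners."""

    def r(x: float) -> float:
        if precision is None:
            return x
        return float(format_minutes(x, precision))

    ms_saving, dns_saving = helicopter_transport_saving(report)
    doc: dict = {"strategies": {}, "deltas_vs_alvo": {}, "winners": {}}
    for s in STRATEGY_ORDER:
        tl = report.timelines[s]
        doc["strategies"][s.value] = {
            "milestones": [{"label": lab, "minutes": r(t)} for lab, t in tl.milestones],
            "arrival_psc": None if tl.arrival_psc is None else r(tl.arrival_psc),
            "arrival_csc": r(tl.arrival_csc),
            "time_to_ivt": r(tl.time_to_ivt),
            "time_to_evt": r(tl.time_to_evt),
            "total_on_scene": r(tl.total_on_scene),
        }
    for endpoint in ("ivt", "evt"):
        doc["deltas_vs_alvo"][endpoint] = {
            s.value: r(d) for s, d in report.deltas_vs_alvo(endpoint).items()
        }
        doc["winners"][endpoint] = report.fastest(endpoint).value
    doc["helicopter_saving_csc_arrival"] = {"MS": r(ms_saving), "DNS": r(dns_saving)}
    return doc


def write_report_json(
    report: ComparisonReport, path: Union[str, Path], precision: Optional[int] = None
) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report, precision), indent=2) + "\n")


def write_cells_geojson(cells: Sequence[ReachabilityCell], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(cells_to_geojson(cells), indent=2) + "\n")


def write_cells_csv(cells: Sequence[ReachabilityCell], path: Union[str, Path]) -> None:
    """Long format: one row per (cell, strategy, endpoint)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lat", "lon", "strategy", "endpoint", "minutes", "winner"])
        for c in cells:
            for endpoint, times, winner in (
                ("ivt", c.time_to_ivt, c.winner_ivt),
                ("evt", c.time_to_evt, c.winner_evt),
            ):
                for s in STRATEGY_ORDER:
                    writer.writerow(
                        [c.center.lat, c.center.lon, s.value, endpoint,
                         times[s], "1" if s is winner else "0"]
                    )
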