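"""Strategy comparison report, reachability maps, Monte-Carlo sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stroketriage import (
    STRATEGY_ORDER,
    GeoPoint,
    PointRole,
    ScenarioParameters,
    StrategyKind,
    compare_strategies,
    helicopter_transport_saving,
    monte_carlo_sensitivity,
    reachability_map,
)
from stroketriage.comparison import evaluate_cell

durations = hst.floats(min_value=0.0, max_value=300.0, allow_nan=False)
param_sets = hst.builds(
    ScenarioParameters,
    **{name: durations for name in ScenarioParameters.field_names()},
)


class TestComparisonReport:
    def test_case_deltas(self, case_params):
        """aLVO-guided dispatch: IVT 6 min before DnS and 22 before MS-air;
        EVT 47 min before DnS-air and 22 before MS-air."""
        rep = compare_strategies(case_params)
        ivt = rep.deltas_vs_alvo("ivt")
        evt = rep.deltas_vs_alvo("evt")
        assert ivt[StrategyKind.DNS_AIR] == 6
        assert ivt[StrategyKind.DNS_GROUND] == 6
        assert ivt[StrategyKind.MS_AIR] == 22
        assert evt[StrategyKind.DNS_AIR] == 47
        assert evt[StrategyKind.MS_AIR] == 22

    def test_case_winner_both_endpoints(self, case_params):
        rep = compare_strategies(case_params)
        assert rep.fastest("ivt") is StrategyKind.ALVO_DISPATCH
        assert rep.fastest("evt") is StrategyKind.ALVO_DISPATCH

    def test_degenerate_zero_travel_ties(self):
        """With every prehospital segment zero and shared in-hospital
        defaults, the three direct-to-CSC strategies tie on both endpoints."""
        p = ScenarioParameters(
            **{name: 0.0 for name in ScenarioParameters.field_names()}
        ).replace(door_to_needle=30.0, needle_to_groin=60.0,
                  door_to_groin=60.0, needle_to_door=30.0)
        rep = compare_strategies(p)
        for ep in ("ivt", "evt"):
            times = rep._endpoint(ep)
            assert (
                times[StrategyKind.ALVO_DISPATCH]
                == times[StrategyKind.MS_AIR]
                == times[StrategyKind.MS_GROUND]
            )
        assert rep.delta(StrategyKind.MS_GROUND, StrategyKind.ALVO_DISPATCH, "ivt") == 0
        # tie resolved by fixed order
        assert rep.fastest("ivt") is StrategyKind.ALVO_DISPATCH

    @settings(max_examples=100, derandomize=True)
    @given(params=param_sets)
    def test_delta_antisymmetry(self, params):
        rep = compare_strategies(params)
        for a in STRATEGY_ORDER:
            for b in STRATEGY_ORDER:
                for ep in ("ivt", "evt"):
                    assert rep.delta(a, b, ep) == pytest.approx(-rep.delta(b, a, ep))

    @settings(max_examples=100, derandomize=True)
    @given(params=param_sets)
    def test_winner_is_minimum(self, params):
        rep = compare_strategies(params)
        for ep in ("ivt", "evt"):
            best = rep.fastest(ep)
            times = rep._endpoint(ep)
            assert all(times[best] <= times[s] for s in STRATEGY_ORDER)

    @settings(max_examples=100, derandomize=True)
    @given(params=param_sets)
    def test_report_recomputable_from_timelines(self, params):
        """Every report number follows from its five timelines alone."""
        rep = compare_strategies(params)
        for s in STRATEGY_ORDER:
            tl = rep.timelines[s]
            assert rep.time_to_ivt[s] == tl.time_to_ivt
            assert rep.time_to_evt[s] == tl.time_to_evt
        ms, dns = helicopter_transport_saving(rep)
        assert ms == rep.timelines[StrategyKind.MS_GROUND].arrival_csc - \
            rep.timelines[StrategyKind.MS_AIR].arrival_csc
        assert dns == rep.timelines[StrategyKind.DNS_GROUND].arrival_csc - \
            rep.timelines[StrategyKind.DNS_AIR].arrival_csc


class TestHelicopterSaving:
    def test_case_savings(self, case_params):
        """Ground-to-air switch saves 14 min (mothership) and 27 (drip-and-ship)
        on CSC arrival."""
        assert helicopter_transport_saving(compare_strategies(case_params)) == (14, 27)

    @settings(max_examples=100, derandomize=True)
    @given(params=param_sets)
    def test_savings_match_direct_subtraction(self, params):
        rep = compare_strategies(params)
        ms, dns = helicopter_transport_saving(rep)
        assert ms == pytest.approx(
            rep.timelines[StrategyKind.MS_GROUND].milestones[-1][1]
            - rep.timelines[StrategyKind.MS_AIR].milestones[-1][1]
        )
        assert dns == pytest.approx(
            rep.timelines[StrategyKind.DNS_GROUND].milestones[-1][1]
            - rep.timelines[StrategyKind.DNS_AIR].milestones[-1][1]
        )


class TestReachability:
    def test_single_cell_at_case_scene(self, case_geography, case_params):
        """One cell placed at the case scene, with the measured override
        table, picks aLVO-guided dispatch for both endpoints."""
        scene = next(p for p in case_geography.points if p.role is PointRole.SCENE)
        cells = reachability_map(
            case_geography.points,
            (scene.lat, scene.lon, scene.lat, scene.lon),
            0.1,
            case_params,
            case_geography.models,
            case_geography.overrides,
        )
        assert len(cells) == 1
        assert cells[0].winner_ivt is StrategyKind.ALVO_DISPATCH
        assert cells[0].winner_evt is StrategyKind.ALVO_DISPATCH
        assert cells[0].time_to_ivt[StrategyKind.ALVO_DISPATCH] == 111

    def test_cell_on_csc_tie_break(self, case_params):
        """A scene co-located with every facility: the direct strategies tie
        and the fixed order picks aLVO-guided dispatch."""
        points = [
            GeoPoint(47.0, 8.0, PointRole.CSC, "csc"),
            GeoPoint(47.0, 8.0, PointRole.PSC, "psc"),
            GeoPoint(47.0, 8.0, PointRole.EMS_BASE, "ems"),
            GeoPoint(47.0, 8.0, PointRole.HEMS_BASE, "hems"),
        ]
        cells = reachability_map(points, (47.0, 8.0, 47.0, 8.0), 0.1, case_params)
        [cell] = cells
        ivt = cell.time_to_ivt
        # at zero distance ground beats air on overhead; the aLVO timeline
        # still wins or ties MS_GROUND only through tie-break when equal
        assert cell.winner_ivt == min(
            STRATEGY_ORDER, key=lambda s: (ivt[s], STRATEGY_ORDER.index(s))
        )

    def test_grid_cells_match_single_cell_runs(self, case_geography, case_params):
        """Each cell of a 3x3 grid equals an independent one-cell evaluation."""
        bbox = (47.9, 8.0, 48.1, 8.2)
        cells = reachability_map(
            case_geography.points, bbox, 0.1, case_params,
            case_geography.models, case_geography.overrides,
        )
        assert len(cells) == 9
        facilities = [p for p in case_geography.points if p.role is not PointRole.SCENE]
        for cell in cells:
            solo = evaluate_cell(
                cell.center, facilities, case_params,
                case_geography.models, case_geography.overrides,
            )
            assert solo.time_to_ivt == cell.time_to_ivt
            assert solo.time_to_evt == cell.time_to_evt
            assert solo.winner_ivt is cell.winner_ivt
            assert solo.winner_evt is cell.winner_evt

    def test_empty_grid_rejected(self, case_geography, case_params):
        with pytest.raises(ValueError):
            reachability_map(
                case_geography.points, (48.0, 8.0, 47.0, 8.2), 0.1, case_params
            )
        with pytest.raises(ValueError, match="step"):
            reachability_map(
                case_geography.points, (47.0, 8.0, 48.0, 8.2), 0.0, case_params
            )

    def test_alvo_advantage_grows_with_distance(self, case_params):
        """Qualitative check: moving the scene farther from the CSC (and the
        helicopter base with it) widens the aLVO-vs-MS-air EVT gap or keeps
        it equal — the parallel-dispatch advantage does not shrink with
        distance."""
        facilities = [
            GeoPoint(48.0, 9.0, PointRole.CSC, "csc"),
            GeoPoint(48.0, 8.4, PointRole.PSC, "psc"),
            GeoPoint(48.0, 8.1, PointRole.EMS_BASE, "ems"),
            GeoPoint(48.0, 8.0, PointRole.HEMS_BASE, "hems"),
        ]
        gaps = []
        for lon in (8.2, 7.9, 7.6, 7.3):
            cell = evaluate_cell(
                GeoPoint(48.0, lon, PointRole.SCENE, "cell"), facilities, case_params
            )
            gaps.append(
                cell.time_to_evt[StrategyKind.MS_AIR]
                - cell.time_to_evt[StrategyKind.ALVO_DISPATCH]
            )
        assert all(b >= a - 1e-9 for a, b in zip(gaps, gaps[1:]))


class TestMonteCarlo:
    def test_degenerate_fixed_distributions(self, case_params):
        dists = {"scene_to_csc_ground": ("fixed", 50.0)}
        out = monte_carlo_sensitivity(dists, n=10, seed=0, base_params=case_params)
        key = "ivt_delta_vs_alvo:DNS_AIR"
        assert out[key]["mean"] == 6.0
        assert out[key]["p2.5"] == out[key]["p97.5"] == 6.0

    def test_seed_determinism(self, case_params):
        dists = {"scene_to_csc_ground": ("uniform", 40.0, 80.0),
                 "on_scene": ("triangular", 20.0, 30.0, 45.0)}
        a = monte_carlo_sensitivity(dists, n=50, seed=123, base_params=case_params)
        b = monte_carlo_sensitivity(dists, n=50, seed=123, base_params=case_params)
        assert a == b

    def test_affine_expectation(self, case_params):
        """The MS-ground EVT delta is affine in scene_to_csc_ground, so its
        Monte-Carlo mean under uniform(40, 80) equals the closed-form value
        at the midpoint, up to Monte-Carlo error."""
        rep_lo = compare_strategies(case_params.replace(scene_to_csc_ground=40.0))
        rep_hi = compare_strategies(case_params.replace(scene_to_csc_ground=80.0))
        d_lo = rep_lo.delta(StrategyKind.MS_GROUND, StrategyKind.ALVO_DISPATCH, "evt")
        d_hi = rep_hi.delta(StrategyKind.MS_GROUND, StrategyKind.ALVO_DISPATCH, "evt")
        closed_form = (d_lo + d_hi) / 2.0
        # MC error: delta slope is 1 min per min of travel; sd = 40/sqrt(12)
        se = (40.0 / np.sqrt(12.0)) / np.sqrt(1000)
        out = monte_carlo_sensitivity(
            {"scene_to_csc_ground": ("uniform", 40.0, 80.0)},
            n=1000, seed=7, base_params=case_params,
        )
        assert abs(out["evt_delta_vs_alvo:MS_GROUND"]["mean"] - closed_form) < 4 * se

    def test_reversed_bounds_rejected(self, case_params):
        with pytest.raises(ValueError, match="reversed"):
            monte_carlo_sensitivity(
                {"on_scene": ("uniform", 50.0, 10.0)}, n=5, seed=0,
                base_params=case_params,
            )

    def test_affine_with_single_breakpoint(self, case_params):
        """Each endpoint time is piecewise affine in any single parameter with
        at most one slope change (the aLVO max() breakpoint)."""
        for field in ("hems_base_to_scene", "on_scene", "scene_to_csc_ground"):
            for strategy in STRATEGY_ORDER:
                xs = np.linspace(0.0, 120.0, 241)
                ys = []
                for x in xs:
                    from stroketriage import build_timeline
                    tl = build_timeline(strategy, case_params.replace(**{field: float(x)}))
                    ys.append(tl.time_to_evt)
                slopes = np.round(np.diff(ys) / np.diff(xs), 9)
                assert len(set(slopes.tolist())) <= 2  # at most one breakpoint
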