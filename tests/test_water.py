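import numpy as np
import pandas as pd
import pytest

from landes.landscape import SyntheticConfig, generate_synthetic_landscape
from landes.water_purification import (Raindrop, accumulate_river,
                                       calibrate_export_coefficients,
                                       cell_loading, cell_runoff,
                                       d8_flow_directions,
                                       default_water_params,
                                       extract_river_network, fill_sinks,
                                       latin_hypercube_sample, route_overland,
                                       run_water_year, rusle_erosion, FlowField,
                                       OUTLET)

from conftest import make_landscape


# ---------------------------------------------------------------------------
# DEM conditioning and D8 routing
# ---------------------------------------------------------------------------


def walk_to_edge(flow, r, c):
    """Follow D8 until the flow leaves the grid; return the path."""
    path = [(r, c)]
    while True:
        nxt = flow.downstream(*path[-1])
        if nxt is None:
            return path
        assert nxt not in path, "cycle in flow field"
        path.append(nxt)


class TestFillSinks:
    def test_drainable_plane_unchanged(self):
        dem = np.tile(np.arange(5.0), (4, 1))  # rises to the east
        np.testing.assert_array_equal(fill_sinks(dem), dem)

    def test_single_pit_raised_to_rim(self):
        dem = np.full((3, 3), 10.0)
        dem[1, 1] = 2.0
        filled = fill_sinks(dem)
        assert filled[1, 1] == pytest.approx(10.0 + 1e-6)

    def test_filled_dem_never_below_input(self):
        rng = np.random.default_rng(0)
        dem = rng.uniform(0, 100, size=(12, 12))
        assert np.all(fill_sinks(dem) >= dem)

    def test_every_cell_drains_to_an_edge(self):
        rng = np.random.default_rng(1)
        dem = rng.uniform(0, 100, size=(10, 10))
        flow = d8_flow_directions(fill_sinks(dem))
        for r in range(10):
            for c in range(10):
                end = walk_to_edge(flow, r, c)[-1]
                assert end[0] in (0, 9) or end[1] in (0, 9)

    def test_nonfinite_dem_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fill_sinks(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestD8:
    def test_west_tilted_plane_flows_west(self):
        dem = np.tile(np.arange(5.0), (4, 1))
        flow = d8_flow_directions(dem)
        assert np.all(flow.directions[:, 1:] == 4)  # W
        assert np.all(flow.directions[:, 0] == OUTLET)

    def test_line_accumulation_counts_upstream_cells(self):
        dem = np.array([np.arange(5.0)])
        flow = d8_flow_directions(dem)
        assert flow.accumulation[0, 0] == 5.0

    def test_outlet_accumulation_conserves_cell_count(self):
        rng = np.random.default_rng(2)
        dem = fill_sinks(rng.uniform(0, 50, size=(8, 8)))
        flow = d8_flow_directions(dem)
        outlet_total = flow.accumulation[flow.directions == OUTLET].sum()
        assert outlet_total == 64.0

    def test_accumulation_matches_path_walking_oracle(self):
        rng = np.random.default_rng(3)
        dem = fill_sinks(rng.uniform(0, 50, size=(7, 7)))
        flow = d8_flow_directions(dem)
        counts = np.zeros((7, 7))
        for r in range(7):
            for c in range(7):
                for rc in walk_to_edge(flow, r, c):
                    counts[rc] += 1
        np.testing.assert_array_equal(flow.accumulation, counts)


class TestRiverNetwork:
    def test_threshold_one_marks_every_cell(self):
        dem = np.tile(np.arange(5.0), (4, 1))
        net = extract_river_network(d8_flow_directions(dem), 1)
        assert len(net.river_cells) == 20

    def test_v_valley_has_single_mainstem(self):
        # valley floor along row 2 of a 5x8 DEM falling to the east
        dem = np.zeros((5, 8))
        for r in range(5):
            for c in range(8):
                dem[r, c] = 100 - 5 * c + 10 * abs(r - 2)
        flow = d8_flow_directions(fill_sinks(dem))
        net = extract_river_network(flow, threshold=6)
        assert net.river_cells and all(r == 2 for r, _ in net.river_cells)

    def test_link_count_is_rivers_minus_outlets(self):
        rng = np.random.default_rng(4)
        dem = fill_sinks(rng.uniform(0, 50, size=(10, 10)))
        flow = d8_flow_directions(dem)
        net = extract_river_network(flow, threshold=4)
        outlets = sum(1 for v in net.downstream.values() if v is None)
        assert net.n_links == len(net.river_cells) - outlets

    def test_empty_network_warns(self):
        dem = np.tile(np.arange(3.0), (3, 1))
        with pytest.warns(UserWarning, match="empty"):
            extract_river_network(d8_flow_directions(dem), 10_000)

    def test_monitoring_point_off_network_rejected(self):
        dem = np.tile(np.arange(5.0), (4, 1))
        flow = d8_flow_directions(dem)
        with pytest.raises(ValueError, match="gauge"):
            extract_river_network(flow, 4, [("gauge", 0, 4)])

    def test_threshold_below_one_rejected(self):
        dem = np.tile(np.arange(3.0), (3, 1))
        with pytest.raises(ValueError, match=">= 1"):
            extract_river_network(d8_flow_directions(dem), 0)


# ---------------------------------------------------------------------------
# Per-cell hydrology
# ---------------------------------------------------------------------------


class TestCellHydrology:
    def test_area_weighted_runoff(self, water_params):
        land = make_landscape(1, 1, {"forest": 0.5, "cropland": 0.5},
                              precipitation=100.0)
        params = default_water_params()
        params.runoff["forest"] = 0.2
        params.runoff["cropland"] = 0.4
        depth, volume = cell_runoff(land.cell(0, 0), params, land.cell_area)
        assert depth == pytest.approx(30.0)
        assert volume == pytest.approx(30.0 / 1000 * 64.0 * 1e4)

    def test_runoff_bounded_by_precipitation(self, synth20, water_params):
        land = synth20.landscape
        for cell in land.iter_cells():
            depth, _ = cell_runoff(cell, water_params, land.cell_area)
            assert 0.0 <= depth <= cell.precipitation + 1e-9

    def test_loading_arithmetic(self):
        land = make_landscape(1, 1, {"cropland": 1.0}, precipitation=450.0)
        params = default_water_params()
        params.export["plains"]["cropland"]["P"] = 0.01
        loads = cell_loading(land.cell(0, 0), params)
        assert loads["P"] == pytest.approx(450.0 * 64.0 * 0.01)  # 288 kg

    def test_loading_linear_in_precipitation(self, water_params):
        land = make_landscape(1, 1, {"cropland": 0.4, "pasture": 0.6},
                              precipitation=100.0)
        base = cell_loading(land.cell(0, 0), water_params)
        land.cell(0, 0).precipitation = 200.0
        double = cell_loading(land.cell(0, 0), water_params)
        for s in ("N", "P", "TSS"):
            assert double[s] == pytest.approx(2 * base[s])

    def test_zero_precipitation_zero_loads(self, water_params):
        land = make_landscape(1, 1, {"cropland": 1.0}, precipitation=0.0)
        assert all(v == 0.0 for v in cell_loading(land.cell(0, 0),
                                                  water_params).values())

    def test_missing_export_coefficient_named(self):
        land = make_landscape(1, 1, {"cropland": 1.0})
        params = default_water_params()
        del params.export["plains"]["cropland"]
        with pytest.raises(ValueError, match="cropland"):
            cell_loading(land.cell(0, 0), params)


class TestRusle:
    def test_factor_product(self):
        assert rusle_erosion(100, 0.3, 1.2, 0.2, 1.0, 1.0) == pytest.approx(7.2)

    def test_undisturbed_cover_zero(self):
        assert rusle_erosion(100, 0.3, 1.2, 0.0, 1.0, 64.0) == 0.0

    def test_linear_in_each_factor(self):
        base = rusle_erosion(50, 0.3, 1.0, 0.2, 1.0, 10.0)
        assert rusle_erosion(100, 0.3, 1.0, 0.2, 1.0, 10.0) == pytest.approx(2 * base)
        assert rusle_erosion(50, 0.6, 1.0, 0.2, 1.0, 10.0) == pytest.approx(2 * base)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError, match="K"):
            rusle_erosion(1.0, -0.1, 1.0, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Overland routing
# ---------------------------------------------------------------------------


class TestRouteOverland:
    def test_origin_adjacent_to_river_no_attenuation(self):
        land = make_landscape(1, 3, {"forest": 1.0},
                              elevation_fn=lambda r, c: float(c))
        flow = d8_flow_directions(land.elevations())
        params = default_water_params()
        drop = Raindrop(origin=(0, 1), volume=5.0, loads={"P": 100.0})
        entry, delivered, removals = route_overland(drop, flow, land, params,
                                                    river_cells={(0, 0)})
        assert entry == (0, 0)
        assert delivered["P"] == 100.0 and removals == []

    def test_multiplicative_attenuation_chain(self):
        land = make_landscape(1, 4, {"forest": 1.0},
                              elevation_fn=lambda r, c: float(c))
        params = default_water_params()
        params.retention["forest"] = {"P": 0.5, "N": 0.5, "TSS": 0.5,
                                      "sediment": 0.5}
        # transit cells are (0,2) and (0,1); make their retentions differ
        land.cell(0, 1).comp = {"cropland": 64.0}
        params.retention["cropland"] = {"P": 0.2, "N": 0.2, "TSS": 0.2,
                                        "sediment": 0.2}
        flow = d8_flow_directions(land.elevations())
        drop = Raindrop(origin=(0, 3), volume=1.0, loads={"P": 100.0})
        entry, delivered, removals = route_overland(drop, flow, land, params,
                                                    river_cells={(0, 0)})
        assert entry == (0, 0)
        assert delivered["P"] == pytest.approx(100 * 0.5 * 0.8)  # 40 kg
        assert removals[0][1]["P"] == pytest.approx(50.0)
        assert removals[1][1]["P"] == pytest.approx(10.0)

    def test_total_retention_delivers_nothing(self):
        land = make_landscape(1, 3, {"forest": 1.0},
                              elevation_fn=lambda r, c: float(c))
        params = default_water_params()
        params.retention["forest"] = {s: 1.0 for s in ("N", "P", "TSS", "sediment")}
        flow = d8_flow_directions(land.elevations())
        drop = Raindrop(origin=(0, 2), volume=1.0, loads={"P": 10.0})
        _, delivered, _ = route_overland(drop, flow, land, params, {(0, 0)})
        assert delivered["P"] == 0.0

    def test_cycle_detection(self):
        land = make_landscape(1, 2, {"forest": 1.0})
        directions = np.array([[0, 4]], dtype=np.int8)  # E then W: a 2-cycle
        flow = FlowField(directions=directions, filled=np.zeros((1, 2)),
                         order=np.array([0, 1]), accumulation=np.ones((1, 2)))
        drop = Raindrop(origin=(0, 0), volume=1.0, loads={"P": 1.0})
        with pytest.raises(RuntimeError, match="loop"):
            route_overland(drop, flow, land, default_water_params(), set())

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Raindrop(origin=(0, 0), volume=1.0, loads={"P": -1.0})


class TestAccumulateRiver:
    def _random_case(self, seed, size):
        rng = np.random.default_rng(seed)
        dem = fill_sinks(rng.uniform(0, 50, size=size))
        flow = d8_flow_directions(dem)
        net = extract_river_network(flow, threshold=2)
        entries = rng.uniform(0, 10, size=size)
        off_river = np.ones(size, dtype=bool)
        for rc in net.river_cells:
            off_river[rc] = False
        entries[off_river] = 0.0
        return flow, net, entries

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_upstream_set_oracle(self, seed):
        flow, net, entries = self._random_case(seed, (6, 6))
        assert len(net.river_cells) <= 50
        acc = accumulate_river(net, {"x": entries})["x"]
        # oracle: for each river cell, sum entries over its upstream river set
        upstream = {rc: {rc} for rc in net.river_cells}
        for rc in net.river_cells:
            cur = rc
            while net.downstream[cur] is not None:
                cur = net.downstream[cur]
                upstream[cur].add(rc)
        for rc in net.river_cells:
            expected = sum(entries[u] for u in upstream[rc])
            assert acc[rc] == pytest.approx(expected)

    def test_confluence_additivity(self):
        # two tributaries joining: 10 + 5 below the confluence
        dem = np.array([[5.0, 9.0, 5.0],
                        [9.0, 1.0, 9.0],
                        [9.0, 0.0, 9.0]])
        flow = d8_flow_directions(fill_sinks(dem))
        net = extract_river_network(flow, threshold=1)
        entries = np.zeros((3, 3))
        entries[0, 0] = 10.0
        entries[0, 2] = 5.0
        acc = accumulate_river(net, {"p": entries})["p"]
        assert acc[2, 1] == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# Full water year
# ---------------------------------------------------------------------------


class TestRunWaterYear:
    def test_mass_conservation_per_substance(self, synth20, water_params):
        result = run_water_year(synth20.landscape, water_params,
                                synth20.config.river_threshold,
                                synth20.monitoring_points)
        for s in ("N", "P", "TSS", "sediment"):
            loading = result.loading[s].sum()
            assert loading > 0
            balance = result.supplied[s].sum() + result.removal[s].sum()
            assert abs(loading - balance) <= 1e-9 * loading

    def test_outlet_flow_equals_upstream_runoff_oracle(self, synth20,
                                                       water_params):
        result = run_water_year(synth20.landscape, water_params,
                                synth20.config.river_threshold,
                                synth20.monitoring_points)
        label, r, c = next(p for p in synth20.monitoring_points
                           if p[0] == "outlet")
        # brute force: every cell whose D8 path hits (r, c)'s upstream river set
        flow, net = result.flow, result.network
        total = 0.0
        for cell in synth20.landscape.iter_cells():
            path = [(cell.row, cell.col)]
            while True:
                if path[-1] in net.river_cells:
                    # continue along the river to see if it passes the gauge
                    cur = path[-1]
                    while cur is not None:
                        if cur == (r, c):
                            total += result.runoff_volume[cell.row, cell.col]
                            cur = None
                        else:
                            cur = net.downstream[cur]
                    break
                nxt = flow.downstream(*path[-1])
                if nxt is None:
                    break
                path.append(nxt)
        assert result.river_flow[r, c] == pytest.approx(total)

    def test_zero_precipitation_all_zero(self, water_params):
        land = make_landscape(8, 8, {"forest": 0.5, "cropland": 0.5},
                              precipitation=0.0,
                              elevation_fn=lambda r, c: float(c))
        result = run_water_year(land, water_params, river_threshold=4)
        for s in ("N", "P", "TSS", "sediment"):
            assert result.loading[s].sum() == 0.0
            assert result.supplied[s].sum() == 0.0
        assert result.runoff_volume.sum() == 0.0

    def test_more_cropland_weakly_increases_downstream_p(self, water_params):
        def build(crop_fraction):
            land = make_landscape(6, 6, {"pasture": 1.0},
                                  elevation_fn=lambda r, c: float(c) + 0.01 * r)
            target = land.cell(2, 4)  # upstream cell
            target.comp = {"pasture": (1 - crop_fraction) * 64.0,
                           "cropland": crop_fraction * 64.0}
            return land

        results = []
        for frac in (0.0, 0.5, 1.0):
            land = build(frac)
            res = run_water_year(land, water_params, river_threshold=6)
            results.append(res.supplied["P"].sum())
        assert results[0] <= results[1] <= results[2]
        assert results[0] < results[2]


# ---------------------------------------------------------------------------
# Latin Hypercube sampling and calibration
# ---------------------------------------------------------------------------


class TestLatinHypercube:
    def test_single_sample_within_range(self):
        (sample,) = latin_hypercube_sample({"a": (2.0, 4.0)}, 1, seed=0)
        assert 2.0 <= sample["a"] <= 4.0

    def test_each_parameter_occupies_each_decile_once(self):
        ranges = {"a": (0.0, 1.0), "b": (10.0, 30.0), "c": (-5.0, 5.0)}
        samples = latin_hypercube_sample(ranges, 10, seed=1)
        for name, (lo, hi) in ranges.items():
            strata = sorted(int((s[name] - lo) / (hi - lo) * 10) for s in samples)
            assert strata == list(range(10))

    def test_same_seed_same_design(self):
        ranges = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        assert latin_hypercube_sample(ranges, 5, seed=3) == \
            latin_hypercube_sample(ranges, 5, seed=3)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nverted"):
            latin_hypercube_sample({"a": (1.0, 0.0)}, 5, seed=0)

    def test_zero_sets_rejected(self):
        with pytest.raises(ValueError, match="n_sets"):
            latin_hypercube_sample({"a": (0.0, 1.0)}, 0, seed=0)


def _candidates(base, scales):
    out = []
    for k in scales:
        export = {g: {cls: {s: v * k for s, v in subs.items()}
                      for cls, subs in classes.items()}
                  for g, classes in base.export.items()}
        out.append(base.with_export(export))
    return out


@pytest.fixture(scope="module")
def calibration_setting():
    synth = generate_synthetic_landscape(SyntheticConfig(n_rows=15,
                                                         n_cols=15), seed=9)
    base = default_water_params()
    candidates = _candidates(base, [0.5, 0.7, 0.9, 1.0, 1.1, 1.3, 1.5,
                                    1.7, 1.9, 2.1])
    truth_index = 5
    truth = candidates[truth_index]
    observed_run = run_water_year(synth.landscape, truth,
                                  synth.config.river_threshold,
                                  synth.monitoring_points)
    observed = observed_run.monitoring.melt(
        id_vars=["point"], value_vars=["P"], var_name="substance",
        value_name="load_kg")
    groups = {label: (label if label in ("mountains", "foothills", "plains")
                      else "plains") for label, _, _ in
              synth.monitoring_points}
    return synth, candidates, truth_index, observed, groups


class TestCalibration:

    def test_generating_set_recovered_per_region(self, calibration_setting):
        synth, candidates, truth_index, observed, groups = calibration_setting
        result = calibrate_export_coefficients(
            synth.landscape, observed, candidates, synth.monitoring_points,
            groups, synth.config.river_threshold)
        assert all(idx == truth_index for idx in result.best_index.values())
        best_rows = result.objective[result.objective["candidate"] == truth_index]
        assert (best_rows["rmse"] < 1e-9).all()

    def test_single_candidate_returned_trivially(self, calibration_setting):
        synth, candidates, truth_index, observed, groups = calibration_setting
        result = calibrate_export_coefficients(
            synth.landscape, observed, [candidates[0]], synth.monitoring_points,
            groups, synth.config.river_threshold)
        assert set(result.best_index.values()) == {0}

    def test_objective_invariant_to_point_ordering(self, calibration_setting):
        synth, candidates, truth_index, observed, groups = calibration_setting
        shuffled = list(reversed(synth.monitoring_points))
        a = calibrate_export_coefficients(synth.landscape, observed,
                                          candidates[:3],
                                          synth.monitoring_points, groups,
                                          synth.config.river_threshold)
        b = calibrate_export_coefficients(synth.landscape, observed,
                                          candidates[:3], shuffled, groups,
                                          synth.config.river_threshold)
        merged = a.objective.merge(b.objective, on=["candidate", "group"])
        assert np.allclose(merged["rmse_x"], merged["rmse_y"])

    def test_no_observations_rejected(self, calibration_setting):
        synth, candidates, _, _, groups = calibration_setting
        with pytest.raises(ValueError, match="observations"):
            calibrate_export_coefficients(
                synth.landscape, pd.DataFrame(), candidates,
                synth.monitoring_points, groups)
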