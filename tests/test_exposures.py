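"""The eight walkability metrics against hand/oracle computations."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

import walkbmi as w
from walkbmi.errors import DegenerateInputError, LayerError
from walkbmi.spatial import NetworkBuffer, ReachedPortion

from conftest import straight_road


def make_buffer(portions, area_km2=None, origin=Point(0, 0)):
    """NetworkBuffer with fabricated contents for direct formula checks.

    ``portions`` is a list of (length_m, attrs) tuples laid end-to-end on
    the x-axis; ``area_km2`` optionally forces the polygon to a rectangle
    of exactly that area.
    """
    x = 0.0
    reached = []
    for length, attrs in portions:
        seg_attrs = dict(speed_limit=25.0, adt=0.0, sidewalk_code=2)
        seg_attrs.update(attrs)
        geom = LineString([(x, 0), (x + length, 0)])
        seg = w.StreetSegment(f"f{len(reached)}", geom, **seg_attrs)
        reached.append(ReachedPortion(seg, geom))
        x += length
    if area_km2 is not None:
        poly = box(0, 0, area_km2 * 1e6 / 1000.0, 1000.0)
    else:
        poly = box(0, -50, max(x, 1.0), 50)
    return NetworkBuffer(origin=origin, radius=800, offset=50, reached=reached, polygon=poly)


class TestLandUseMix:
    def equal_mix_layer(self, k=3):
        pts = []
        for c in w.BUSINESS_CATEGORIES:
            pts.extend(w.BusinessPoint(Point(10 + len(pts), 0), c) for _ in range(k))
        return w.BusinessLayer(tuple(pts))

    def test_equal_mixture_is_exactly_one(self):
        buf = make_buffer([(100, {})])
        mix, empty = w.land_use_mix(buf, self.equal_mix_layer())
        assert mix == 1.0 and not empty

    def test_single_category_is_exactly_zero(self):
        pts = tuple(w.BusinessPoint(Point(10 + i, 0), "food") for i in range(7))
        buf = make_buffer([(100, {})])
        mix, empty = w.land_use_mix(buf, w.BusinessLayer(pts))
        assert mix == 0.0 and not empty

    def test_hand_computed_entropy(self):
        counts = {"food": 2, "retail": 1, "services": 1}
        pts = []
        for cat, n in counts.items():
            pts.extend(w.BusinessPoint(Point(10 + len(pts), 0), cat) for _ in range(n))
        buf = make_buffer([(100, {})])
        mix, _ = w.land_use_mix(buf, w.BusinessLayer(tuple(pts)))
        # p = (0.5, 0.25, 0.25): -(0.5 ln 0.5 + 0.5 ln 0.25) / ln 5
        expected = -(0.5 * math.log(0.5) + 0.5 * math.log(0.25)) / math.log(5)
        assert mix == pytest.approx(expected, abs=1e-9)
        assert mix == pytest.approx(0.6460, abs=5e-4)

    def test_empty_buffer_flagged_zero(self):
        far = w.BusinessLayer((w.BusinessPoint(Point(1e6, 1e6), "food"),))
        buf = make_buffer([(100, {})])
        mix, empty = w.land_use_mix(buf, far)
        assert mix == 0.0 and empty

    def test_relabeling_and_duplication_invariance(self):
        base = {"food": 4, "retail": 2, "physical activity": 1}
        relabeled = {"services": 4, "cultural/educational": 2, "food": 1}

        def layer(counts, dup=1):
            pts = []
            for cat, n in counts.items():
                pts.extend(
                    w.BusinessPoint(Point(10 + len(pts), 0), cat)
                    for _ in range(n * dup)
                )
            return w.BusinessLayer(tuple(pts))

        buf = make_buffer([(100, {})])
        m0, _ = w.land_use_mix(buf, layer(base))
        m1, _ = w.land_use_mix(buf, layer(relabeled))
        m2, _ = w.land_use_mix(buf, layer(base, dup=3))
        assert m0 == pytest.approx(m1, abs=1e-12)
        assert m0 == pytest.approx(m2, abs=1e-12)


class TestSidewalkCompleteness:
    def test_all_both_sides_is_two(self):
        buf = make_buffer([(100, {"sidewalk_code": 2}), (250, {"sidewalk_code": 2})])
        assert w.sidewalk_completeness(buf) == pytest.approx(2.0)

    def test_all_none_is_zero(self):
        buf = make_buffer([(100, {"sidewalk_code": 0})])
        assert w.sidewalk_completeness(buf) == pytest.approx(0.0)

    def test_length_weighted_mean(self):
        buf = make_buffer(
            [(100, {"sidewalk_code": 2}), (300, {"sidewalk_code": 0})]
        )
        assert w.sidewalk_completeness(buf) == pytest.approx(0.5)

    def test_median_roads_excluded(self):
        buf = make_buffer(
            [(100, {"sidewalk_code": 2}), (900, {"sidewalk_code": 0, "has_median": True})]
        )
        assert w.sidewalk_completeness(buf) == pytest.approx(2.0)

    def test_only_median_roads_undefined(self):
        buf = make_buffer([(100, {"has_median": True})])
        with pytest.raises(DegenerateInputError):
            w.sidewalk_completeness(buf)


class TestTrafficDensity:
    def test_zero_adt(self):
        buf = make_buffer([(500, {"adt": 0})], area_km2=0.5)
        assert w.traffic_density(buf) == 0.0

    def test_hand_formula(self):
        buf = make_buffer([(500, {"adt": 1000})], area_km2=0.5)
        assert w.traffic_density(buf) == pytest.approx(1_000_000.0)

    def test_split_invariance(self):
        whole = make_buffer([(500, {"adt": 1000})], area_km2=0.5)
        halves = make_buffer(
            [(250, {"adt": 1000}), (250, {"adt": 1000})], area_km2=0.5
        )
        assert w.traffic_density(whole) == pytest.approx(w.traffic_density(halves))

    def test_inverse_scaling_with_area(self):
        small = make_buffer([(500, {"adt": 1000})], area_km2=0.5)
        large = make_buffer([(500, {"adt": 1000})], area_km2=1.0)
        assert w.traffic_density(small) == pytest.approx(2 * w.traffic_density(large))


class TestAvgSpeedLimit:
    def test_constant(self):
        buf = make_buffer([(100, {"speed_limit": 27}), (900, {"speed_limit": 27})])
        assert w.avg_speed_limit(buf) == pytest.approx(27.0)

    def test_weighted_mean(self):
        buf = make_buffer([(100, {"speed_limit": 20}), (300, {"speed_limit": 40})])
        assert w.avg_speed_limit(buf) == pytest.approx(35.0)

    def test_within_min_max(self):
        rng = np.random.default_rng(3)
        speeds = rng.uniform(15, 45, 6)
        buf = make_buffer([(float(rng.uniform(50, 500)), {"speed_limit": s}) for s in speeds])
        assert min(speeds) <= w.avg_speed_limit(buf) <= max(speeds)


class TestResidentialDensity:
    def layer(self):
        return w.TractLayer(
            (
                w.Tract("t1", box(0, 0, 500, 500), 60_000, 500, 0.25),
                w.Tract("t2", box(500, 0, 1000, 500), 90_000, 0, 0.25),
            )
        )

    def test_direct_division(self):
        dens, tid, inc = w.residential_density(Point(100, 100), self.layer())
        assert dens == pytest.approx(2000.0)
        assert tid == "t1" and inc == 60_000

    def test_zero_units(self):
        dens, _, _ = w.residential_density(Point(700, 100), self.layer())
        assert dens == 0.0

    def test_tract_level_constancy(self):
        d1, _, _ = w.residential_density(Point(10, 10), self.layer())
        d2, _, _ = w.residential_density(Point(490, 490), self.layer())
        assert d1 == d2

    def test_outside_all_tracts(self):
        with pytest.raises(LayerError):
            w.residential_density(Point(5000, 5000), self.layer())


class TestOpenSpace:
    def test_count_empty(self):
        buf = make_buffer([(100, {})])
        layer = w.OpenSpaceLayer((w.OpenSpaceFeature("p", Point(1e6, 0)),))
        assert w.openspace_count(buf, layer) == 0

    def test_boundary_touch_counts(self):
        buf = make_buffer([(100, {})])  # polygon box(0,-50,100,50)
        layer = w.OpenSpaceLayer((w.OpenSpaceFeature("p", Point(100, 50)),))
        assert w.openspace_count(buf, layer) == 1

    def test_hand_placed_parks(self):
        buf = make_buffer([(100, {})])
        layer = w.OpenSpaceLayer(
            (
                w.OpenSpaceFeature("in1", Point(50, 0)),
                w.OpenSpaceFeature("in2", box(90, 40, 200, 200)),  # overlaps corner
                w.OpenSpaceFeature("out", box(300, 300, 400, 400)),
            )
        )
        assert w.openspace_count(buf, layer) == 2

    def test_distance_zero_at_home(self):
        net = straight_road(2000)
        layer = w.OpenSpaceLayer((w.OpenSpaceFeature("p", Point(500, 0)),))
        assert w.nearest_openspace_distance(net, Point(500, 0), layer) == 0.0

    def test_distance_caps_at_15km(self):
        net = straight_road(40_000)
        layer = w.OpenSpaceLayer((w.OpenSpaceFeature("p", Point(39_000, 0)),))
        assert w.nearest_openspace_distance(net, Point(0, 0), layer) == 15.0

    def test_min_over_features_matches_pairwise_distances(self, town):
        # oracle: per-feature pairwise network distance, minimized by hand
        spaces = town.openspace
        home = Point(town.spec.extent / 2 + 35, town.spec.extent / 2 - 10)
        from walkbmi.exposures import _access_point

        per_feature = [
            town.network.network_distance(home, _access_point(town.network, f.geometry))
            + f.geometry.distance(_access_point(town.network, f.geometry))
            for f in spaces.features
        ]
        got = w.nearest_openspace_distance(town.network, home, spaces)
        assert got * 1000 == pytest.approx(min(per_feature), rel=1e-6)

    def test_empty_layer_rejected(self):
        net = straight_road(100)
        with pytest.raises(LayerError):
            w.nearest_openspace_distance(net, Point(0, 0), w.OpenSpaceLayer(()))


class TestIntersectionDensity:
    def test_no_high_degree_nodes(self):
        net = straight_road(100)
        buf = net.service_area(Point(50, 0), radius=40, offset=10)
        assert w.intersection_density(buf, net) == 0.0

    def test_direct_division(self, unit_grid):
        buf = unit_grid.service_area(Point(1.5, 1.5), radius=100, offset=0.5)
        n_inside = sum(
            1 for p in unit_grid.find_intersections(pedestrian_only=True)
            if buf.polygon.covers(p)
        )
        assert n_inside == 12
        assert w.intersection_density(buf, unit_grid) == pytest.approx(
            12 / buf.area_km2
        )

    def test_degree_two_nodes_never_change_value(self):
        # same road, once as one segment and once split into two
        net1 = straight_road(100)
        segs = [
            w.StreetSegment("a", LineString([(0, 0), (50, 0)]), 25, 0, 2),
            w.StreetSegment("b", LineString([(50, 0), (100, 0)]), 25, 0, 2),
        ]
        net2 = w.build_network(segs)
        b1 = net1.service_area(Point(50, 0), radius=40, offset=10)
        b2 = net2.service_area(Point(50, 0), radius=40, offset=10)
        assert w.intersection_density(b1, net1) == w.intersection_density(b2, net2)


class TestProfiles:
    def test_ranges_on_randomized_homes(self, town, home_exposures):
        from walkbmi.exposures import exposure_ranges_ok

        assert exposure_ranges_ok(home_exposures)

    def test_quartile_feasibility(self, home_exposures):
        for col in w.EXPOSURE_COLUMNS:
            assert home_exposures[col].nunique() >= 4

    def test_profile_matches_componentwise_recomputation(self, town, home_exposures):
        # 10 pre-selected homes: the assembled profile equals each metric
        # recomputed directly from a fresh buffer
        import pandas as pd
        from walkbmi.exposures import openspace_access_points

        access = openspace_access_points(town.network, town.openspace)
        for _, row in home_exposures.iloc[:10].iterrows():
            home = Point(row.x, row.y)
            buf = town.network.service_area(home)
            assert row.traffic_density == pytest.approx(w.traffic_density(buf))
            assert row.avg_speed_limit_mph == pytest.approx(w.avg_speed_limit(buf))
            assert row.sidewalk_completeness == pytest.approx(
                w.sidewalk_completeness(buf)
            )
            assert row.intersection_density_per_km2 == pytest.approx(
                w.intersection_density(buf, town.network)
            )
            assert row.openspace_count == w.openspace_count(buf, town.openspace)
            assert row.land_use_mix == pytest.approx(
                w.land_use_mix(buf, town.businesses)[0]
            )
            assert row.openspace_distance_km == pytest.approx(
                w.nearest_openspace_distance(
                    town.network, home, town.openspace, access=access
                )
            )
            dens, tid, inc = w.residential_density(home, town.tracts)
            assert row.residential_density_per_km2 == pytest.approx(dens)
            assert (row.tract_id, row.tract_income_usd) == (tid, pytest.approx(inc))
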