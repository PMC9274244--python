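"""Distance primitives against independent geometric oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from icees_lite import geospatial
from icees_lite.geospatial import (
    EARTH_RADIUS_M,
    haversine_m,
    nearest_source_distance,
    point_segment_distance_m,
    exposure_profile,
)
from icees_lite.model import DomainError, PatientRecord, RoadSegment, SourceRegistry

import datetime as dt

RNG = np.random.default_rng(42)


def spherical_law_of_cosines(a, b):
    """Independent great-circle formula (law of cosines, not haversine)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    c = math.sin(lat1) * math.sin(lat2) + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
    return EARTH_RADIUS_M * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_identity(self):
        assert haversine_m((35.0, -79.0), (35.0, -79.0)) == 0.0

    def test_one_degree_longitude_at_35N(self):
        # one degree of longitude at 35°N is about 91.1 km on the sphere
        d = haversine_m((35.0, -79.0), (35.0, -78.0))
        assert d == pytest.approx(91_100, abs=200)

    def test_symmetry_and_law_of_cosines_agreement(self):
        for _ in range(200):
            a = (RNG.uniform(-85, 85), RNG.uniform(-179, 179))
            b = (a[0] + RNG.uniform(-2, 2), a[1] + RNG.uniform(-2, 2))
            assert haversine_m(a, b) == haversine_m(b, a)
            assert haversine_m(a, b) == pytest.approx(
                spherical_law_of_cosines(a, b), abs=1.0)

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(DomainError):
            haversine_m((95.0, 0.0), (0.0, 0.0))


class TestPointSegmentDistance:
    def test_endpoint_is_zero(self):
        seg = RoadSegment(((35.0, -79.0), (35.1, -79.1)))
        assert point_segment_distance_m((35.0, -79.0), seg) == pytest.approx(0.0, abs=1e-6)

    def test_clamps_beyond_endpoint(self):
        # p lies on the segment's supporting line but beyond endpoint a
        seg = RoadSegment(((35.0, -79.0), (35.0, -78.9)))
        p = (35.0, -79.05)
        assert point_segment_distance_m(p, seg) == pytest.approx(
            haversine_m(p, (35.0, -79.0)), rel=1e-3)

    def test_never_exceeds_endpoint_distances(self):
        for _ in range(100):
            lat = RNG.uniform(30, 40)
            lon = RNG.uniform(-90, -70)
            a = (lat + RNG.uniform(-0.05, 0.05), lon + RNG.uniform(-0.05, 0.05))
            b = (lat + RNG.uniform(-0.05, 0.05), lon + RNG.uniform(-0.05, 0.05))
            if a == b:
                continue
            seg = RoadSegment((a, b))
            d = point_segment_distance_m((lat, lon), seg)
            # projected-plane vs great-circle metrics differ by <0.1% at these scales
            assert d <= haversine_m((lat, lon), a) * 1.001 + 1e-6
            assert d <= haversine_m((lat, lon), b) * 1.001 + 1e-6

    def test_dense_sampling_oracle(self):
        # minimum over 10,001 evenly interpolated points on the segment
        for _ in range(20):
            lat = RNG.uniform(30, 40)
            lon = RNG.uniform(-90, -70)
            a = (lat + RNG.uniform(-0.05, 0.05), lon + RNG.uniform(-0.05, 0.05))
            b = (lat + RNG.uniform(-0.05, 0.05), lon + RNG.uniform(-0.05, 0.05))
            seg = RoadSegment((a, b))
            t = np.linspace(0.0, 1.0, 10_001)
            lats = a[0] + t * (b[0] - a[0])
            lons = a[1] + t * (b[1] - a[1])
            brute = min(haversine_m((lat, lon), (la, lo)) for la, lo in zip(lats, lons))
            assert point_segment_distance_m((lat, lon), seg) == pytest.approx(brute, abs=1.0)

    def test_shapely_planar_oracle(self):
        for _ in range(50):
            p = (RNG.uniform(30, 40), RNG.uniform(-90, -70))
            a = (p[0] + RNG.uniform(-0.1, 0.1), p[1] + RNG.uniform(-0.1, 0.1))
            b = (p[0] + RNG.uniform(-0.1, 0.1), p[1] + RNG.uniform(-0.1, 0.1))
            seg = RoadSegment((a, b))
            xy = geospatial._local_xy(p, np.array([a, b], dtype=float))
            expected = Point(0.0, 0.0).distance(LineString(xy))
            assert point_segment_distance_m(p, seg) == pytest.approx(expected, abs=1e-6)


def random_registry(n_cafo=50, n_landfill=20, n_roads=30, rng=RNG):
    pts = lambda k: [(rng.uniform(34, 37), rng.uniform(-81, -77)) for _ in range(k)]
    roads = []
    for _ in range(n_roads):
        a = (rng.uniform(34, 37), rng.uniform(-81, -77))
        b = (a[0] + rng.uniform(0.001, 0.05), a[1] + rng.uniform(0.001, 0.05))
        roads.append(RoadSegment((a, b)))
    return SourceRegistry(cafo_points=pts(n_cafo), landfill_points=pts(n_landfill),
                          road_segments=roads)


class TestNearestSource:
    def test_source_at_point_is_zero(self):
        registry = SourceRegistry(cafo_points=[(35.0, -79.0)])
        assert nearest_source_distance((35.0, -79.0), registry, "cafo") == 0.0

    def test_empty_registry_absent(self):
        assert nearest_source_distance((35.0, -79.0), SourceRegistry(), "landfill") is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError):
            nearest_source_distance((35.0, -79.0), SourceRegistry(), "volcano")

    @pytest.mark.parametrize("kind", ["cafo", "landfill", "road"])
    def test_equals_exhaustive_scan(self, kind):
        registry = random_registry()
        for _ in range(20):
            p = (RNG.uniform(34, 37), RNG.uniform(-81, -77))
            got = nearest_source_distance(p, registry, kind)
            if kind == "road":
                expect = min(point_segment_distance_m(p, s) for s in registry.road_segments)
            else:
                pts = registry.cafo_points if kind == "cafo" else registry.landfill_points
                expect = min(haversine_m(p, q) for q in pts)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_adding_source_is_monotone(self):
        registry = random_registry(n_cafo=10)
        p = (35.5, -79.0)
        before = nearest_source_distance(p, registry, "cafo")
        registry.cafo_points.append((35.6, -79.1))
        assert nearest_source_distance(p, registry, "cafo") <= before

    def test_translation_consistency(self):
        registry = random_registry(n_cafo=20, n_landfill=5, n_roads=5)
        p = (35.5, -79.0)
        dlat, dlon = 0.01, -0.01
        shifted = SourceRegistry(
            cafo_points=[(a + dlat, b + dlon) for a, b in registry.cafo_points],
            landfill_points=[(a + dlat, b + dlon) for a, b in registry.landfill_points],
            road_segments=[RoadSegment(((s.endpoints[0][0] + dlat, s.endpoints[0][1] + dlon),
                                        (s.endpoints[1][0] + dlat, s.endpoints[1][1] + dlon)))
                           for s in registry.road_segments],
        )
        q = (p[0] + dlat, p[1] + dlon)
        for kind in ("cafo", "landfill", "road"):
            d0 = nearest_source_distance(p, registry, kind)
            d1 = nearest_source_distance(q, shifted, kind)
            assert abs(d1 - d0) / d0 < 1e-3


class TestExposureProfile:
    def _patient(self, **kw):
        defaults = dict(patient_id="p1", birth_date=dt.date(2000, 1, 1))
        defaults.update(kw)
        return PatientRecord(**defaults)

    def test_no_geocode_all_absent(self):
        prof = exposure_profile(self._patient(), random_registry())
        assert prof.dist_cafo_m is None and prof.dist_landfill_m is None
        assert prof.dist_road_m is None and prof.block_population is None

    def test_geopoint_without_timestamp_all_absent(self):
        prof = exposure_profile(
            self._patient(geopoint=(35.0, -79.0)), random_registry())
        assert prof.dist_cafo_m is None

    def test_patient_at_landfill(self):
        registry = SourceRegistry(landfill_points=[(35.0, -79.0)],
                                  cafo_points=[(36.0, -78.0)],
                                  road_segments=[RoadSegment(((36, -78), (36, -77.9)))])
        prof = exposure_profile(
            self._patient(geopoint=(35.0, -79.0), geocode_timestamp=dt.date(2020, 1, 1)),
            registry)
        assert prof.dist_landfill_m == 0.0

    def test_unknown_block_group_population_absent(self):
        registry = SourceRegistry(cafo_points=[(35, -79)], block_groups={"BG-1": 100})
        prof = exposure_profile(
            self._patient(geopoint=(35.0, -79.0), geocode_timestamp=dt.date(2020, 1, 1),
                          block_group_id="BG-unknown"),
            registry)
        assert prof.block_population is None
        assert prof.dist_cafo_m == 0.0

    def test_profile_matches_generator_ground_truth(self, small_population):
        ds, registry, truth = small_population
        checked = 0
        for p in ds.patients:
            expected = truth.true_distances[p.patient_id]
            prof = exposure_profile(p, registry)
            if expected is None:
                assert prof.dist_cafo_m is None
                continue
            assert prof.dist_cafo_m == pytest.approx(expected[0], abs=1.0)
            assert prof.dist_landfill_m == pytest.approx(expected[1], abs=1.0)
            assert prof.dist_road_m == pytest.approx(expected[2], abs=1.0)
            checked += 1
        assert checked > 10
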