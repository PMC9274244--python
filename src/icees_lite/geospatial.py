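"""Patient-level environmental exposure estimates.

Distances are great-circle (haversine on a sphere of radius 6,371,000 m) for
point sources and, for roadway polylines, the minimum point-to-segment
distance computed in a local equirectangular projection centered on the
patient. At the sub-kilometer scales that matter for the distance bins
(50 m roadway bins, 500 m site bins) the spherical/planar approximation
error is orders of magnitude below the bin width.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np

from .model import (
    DomainError,
    ExposureProfile,
    PatientRecord,
    RoadSegment,
    SourceRegistry,
)

EARTH_RADIUS_M = 6_371_000.0

log = logging.getLogger(__name__)

_KINDS = ("cafo", "landfill", "road")


def _check_point(p: tuple[float, float]) -> None:
    lat, lon = p
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise DomainError(f"coordinate out of range: ({lat}, {lon})")


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lat, lon) points."""
    _check_point(a)
    _check_point(b)
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(s)))


def _local_xy(origin: tuple[float, float], pts: np.ndarray) -> np.ndarray:
    """Project (lat, lon) rows to meters in an equirectangular plane centered at origin."""
    lat0, lon0 = map(math.radians, origin)
    lat = np.radians(pts[:, 0])
    lon = np.radians(pts[:, 1])
    x = (lon - lon0) * math.cos(lat0) * EARTH_RADIUS_M
    y = (lat - lat0) * EARTH_RADIUS_M
    return np.column_stack([x, y])


def _point_segments_distance_m(p: tuple[float, float], segs: np.ndarray) -> np.ndarray:
    """Distances from p to each segment in an (n, 4) array of (lat1, lon1, lat2, lon2)."""
    a = _local_xy(p, segs[:, 0:2])
    b = _local_xy(p, segs[:, 2:4])
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    # p projects to the origin of its own local plane
    t = np.clip(np.einsum("ij,ij->i", -a, ab) / np.where(denom == 0.0, 1.0, denom), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.hypot(closest[:, 0], closest[:, 1])


def point_segment_distance_m(p: tuple[float, float], seg: RoadSegment) -> float:
    """Minimum distance in meters from point p to a straight road segment."""
    _check_point(p)
    (a, b) = seg.endpoints
    _check_point(a)
    _check_point(b)
    arr = np.array([[a[0], a[1], b[0], b[1]]], dtype=float)
    return float(_point_segments_distance_m(p, arr)[0])


def nearest_source_distance(
    p: tuple[float, float], registry: SourceRegistry, kind: str
) -> Optional[float]:
    """Distance in meters to the nearest source of the given kind, or None if the registry holds none."""
    if kind not in _KINDS:
        raise DomainError(f"unknown source kind {kind!r}; expected one of {_KINDS}")
    _check_point(p)
    if kind == "road":
        if not registry.road_segments:
            return None
        segs = np.array(
            [[*s.endpoints[0], *s.endpoints[1]] for s in registry.road_segments], dtype=float
        )
        return float(_point_segments_distance_m(p, segs).min())
    points = registry.cafo_points if kind == "cafo" else registry.landfill_points
    if not points:
        return None
    return min(haversine_m(p, q) for q in points)


def exposure_profile(patient: PatientRecord, registry: SourceRegistry) -> ExposureProfile:
    """All three nearest distances plus block population for one patient.

    Patients without both a geopoint and a geocode timestamp get an all-absent
    profile: exposure estimates are only defined for valid geocodes with dates.
    """
    if patient.geopoint is None or patient.geocode_timestamp is None:
        return ExposureProfile()
    population = None
    if patient.block_group_id is not None:
        population = registry.block_groups.get(patient.block_group_id)
        if population is None:
            log.warning("block group %s not in registry; population left absent",
                        patient.block_group_id)
    return ExposureProfile(
        dist_cafo_m=nearest_source_distance(patient.geopoint, registry, "cafo"),
        dist_landfill_m=nearest_source_distance(patient.geopoint, registry, "landfill"),
        dist_road_m=nearest_source_distance(patient.geopoint, registry, "road"),
        block_population=population,
    )


# -- source registry I/O (sources_*.csv, block_groups.csv) --------------------


def write_sources(registry: SourceRegistry, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "sources_cafo.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lat", "lon"])
        w.writerows([[repr(lat), repr(lon)] for lat, lon in registry.cafo_points])
    with open(directory / "sources_landfill.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lat", "lon"])
        w.writerows([[repr(lat), repr(lon)] for lat, lon in registry.landfill_points])
    with open(directory / "sources_roads.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lat1", "lon1", "lat2", "lon2"])
        for seg in registry.road_segments:
            (a, b) = seg.endpoints
            w.writerow([repr(a[0]), repr(a[1]), repr(b[0]), repr(b[1])])
    with open(directory / "block_groups.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["block_group_id", "population"])
        for bg, pop in registry.block_groups.items():
            w.writerow([bg, pop])


def read_sources(directory) -> SourceRegistry:
    directory = Path(directory)
    registry = SourceRegistry()
    for name in ("sources_cafo.csv", "sources_landfill.csv", "sources_roads.csv",
                 "block_groups.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing source file: {directory / name}")
    with open(directory / "sources_cafo.csv", newline="") as fh:
        registry.cafo_points = [(float(r["lat"]), float(r["lon"])) for r in csv.DictReader(fh)]
    with open(directory / "sources_landfill.csv", newline="") as fh:
        registry.landfill_points = [
            (float(r["lat"]), float(r["lon"])) for r in csv.DictReader(fh)
        ]
    with open(directory / "sources_roads.csv", newline="") as fh:
        registry.road_segments = [
            RoadSegment(((float(r["lat1"]), float(r["lon1"])),
                         (float(r["lat2"]), float(r["lon2"]))))
            for r in csv.DictReader(fh)
        ]
    with open(directory / "block_groups.csv", newline="") as fh:
        registry.block_groups = {
            r["block_group_id"]: int(r["population"]) for r in csv.DictReader(fh)
        }
    return registry
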