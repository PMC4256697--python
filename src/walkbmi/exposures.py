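"""The eight walkable built-environment metrics.

For each home location the engine evaluates, on an 800-m line-based network
buffer (50-m centerline offset) unless noted:

1. network distance to the nearest recreational open space (km, capped at 15),
2. count of recreational open spaces intersecting the buffer,
3. residential density of the containing census tract (housing units / km²),
4. traffic density: sum of average daily traffic x road length (m) in the
   buffer, divided by buffer area (km²),
5. average speed limit, length-weighted over road within the buffer (mph),
6. sidewalk completeness: length-weighted mean of the 0/1/2 per-segment
   sidewalk code over non-median roads in the buffer,
7. intersection density: nodes where >= 3 pedestrian-network segments meet,
   per km² of buffer,
8. land use mix: normalized Shannon entropy (base ln 5) of the five business
   category proportions among in-buffer business points — 0 means a single
   category, 1 an equal mixture of all five.

Buffer-based sums and means use reached centerline portions clipped at the
exact network radius, not whole intersecting segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .errors import DegenerateInputError, LayerError
from .layers import BUSINESS_CATEGORIES, BusinessLayer, OpenSpaceLayer, TractLayer
from .spatial import (
    DEFAULT_BUFFER_OFFSET,
    DEFAULT_DISTANCE_CAP,
    DEFAULT_MAX_OFFSET,
    DEFAULT_RADIUS,
    NetworkBuffer,
    StreetNetwork,
)

#: canonical metric column order (matches the descriptive-table ordering)
EXPOSURE_COLUMNS = [
    "openspace_distance_km",
    "openspace_count",
    "residential_density_per_km2",
    "traffic_density",
    "avg_speed_limit_mph",
    "sidewalk_completeness",
    "intersection_density_per_km2",
    "land_use_mix",
]


@dataclass
class ExposureProfile:
    """The eight walkability metrics plus tract covariates for one home."""

    openspace_distance_km: float
    openspace_count: int
    residential_density_per_km2: float
    traffic_density: float
    avg_speed_limit_mph: float
    sidewalk_completeness: float
    intersection_density_per_km2: float
    land_use_mix: float
    tract_id: str
    tract_income_usd: float
    land_use_mix_empty: bool = False  # no businesses in buffer; mix set to 0

    def as_dict(self) -> dict:
        return asdict(self)


def openspace_access_points(net: StreetNetwork, spaces: OpenSpaceLayer) -> list:
    """Project every open-space access point onto the network once.

    The access point of a feature is the point of its geometry nearest to
    the street network; precomputing these makes per-home nearest-distance
    queries a single Dijkstra pass.
    """
    return [
        net.project(_access_point(net, f.geometry), max_offset=math.inf)
        for f in spaces.features
    ]


def nearest_openspace_distance(
    net: StreetNetwork,
    home: Point,
    spaces: OpenSpaceLayer,
    cap_km: float = DEFAULT_DISTANCE_CAP / 1000.0,
    max_offset: float = DEFAULT_MAX_OFFSET,
    access: list | None = None,
) -> float:
    """Network distance from home to the nearest open space, km, capped.

    Each feature's access point is the point of its geometry nearest to the
    street network (polygon boundaries allowed); the result is the minimum
    over features of the along-network distance, truncated at ``cap_km``.
    Pass ``access`` from :func:`openspace_access_points` to reuse the
    feature projections across homes.
    """
    if len(spaces) == 0:
        raise LayerError("open space layer is empty")
    cap_m = cap_km * 1000.0
    if access is None:
        access = openspace_access_points(net, spaces)
    p, dist = net.distances_from(home, cap=cap_m, max_offset=max_offset)
    best = cap_m
    for a in access:
        best = min(best, net.distance_to_projected(p, dist, a))
    return min(best, cap_m) / 1000.0


def _access_point(net: StreetNetwork, geometry) -> Point:
    """Point of ``geometry`` nearest to the network (its nearest segment)."""
    from shapely.ops import nearest_points

    rep = geometry.centroid if not geometry.geom_type == "Point" else geometry
    idx = int(net._tree.nearest(rep))
    seg_geom = net.segments[idx].geometry
    on_feature, _ = nearest_points(geometry, seg_geom)
    return on_feature


def openspace_count(buffer: NetworkBuffer, spaces: OpenSpaceLayer) -> int:
    """Open-space features whose geometry intersects the buffer polygon.

    Boundary-touching features count (closed-region convention); each
    feature counts once however many times it overlaps.
    """
    return sum(1 for f in spaces.features if f.geometry.intersects(buffer.polygon))


def residential_density(home: Point, tracts: TractLayer) -> tuple[float, str, float]:
    """Housing units per km² of the census tract containing the home.

    Returns ``(density, tract_id, median_income)``; raises
    :class:`LayerError` when the home is outside every tract.
    """
    for t in tracts.tracts:
        if t.geometry.covers(home):
            return t.housing_units / t.land_area_km2, t.tract_id, t.median_income
    raise LayerError(
        f"home ({home.x:.1f}, {home.y:.1f}) lies outside every census tract"
    )


def traffic_density(buffer: NetworkBuffer) -> float:
    """Sum over reached portions of ADT x length (m), per km² of buffer."""
    if buffer.area_km2 <= 0:
        raise DegenerateInputError("traffic density undefined for zero-area buffer")
    total = sum(p.segment.adt * p.length for p in buffer.reached)
    return total / buffer.area_km2


def avg_speed_limit(buffer: NetworkBuffer) -> float:
    """Length-weighted mean speed limit (mph) of road within the buffer."""
    wsum = sum(p.length for p in buffer.reached)
    if wsum <= 0:
        raise DegenerateInputError("no road length in buffer for speed-limit average")
    return sum(p.segment.speed_limit * p.length for p in buffer.reached) / wsum


def sidewalk_completeness(buffer: NetworkBuffer) -> float:
    """Length-weighted mean sidewalk code over non-median roads in the buffer.

    0 = no sidewalks, 1 = one side, 2 = both sides on all road segments in
    the buffer.  Roads with a median are excluded; if only median roads are
    reached the score is undefined.
    """
    nonmed = [p for p in buffer.reached if not p.segment.has_median]
    wsum = sum(p.length for p in nonmed)
    if wsum <= 0:
        raise DegenerateInputError(
            "sidewalk completeness undefined: only median roads in buffer"
        )
    return sum(p.segment.sidewalk_code * p.length for p in nonmed) / wsum


def intersection_density(
    buffer: NetworkBuffer, net: StreetNetwork, pedestrian_only: bool = True
) -> float:
    """Intersections (>= 3 incident segments, pedestrian network) per km²."""
    if buffer.area_km2 <= 0:
        raise DegenerateInputError(
            "intersection density undefined for zero-area buffer"
        )
    pts = net.find_intersections(pedestrian_only=pedestrian_only)
    n = sum(1 for p in pts if buffer.polygon.covers(p))
    return n / buffer.area_km2


def land_use_mix(
    buffer: NetworkBuffer, businesses: BusinessLayer
) -> tuple[float, bool]:
    """Normalized entropy of business-category proportions in the buffer.

    -sum p_i ln p_i / ln 5 over the five category proportions among
    in-buffer points; zero-count categories contribute 0.  A buffer with no
    businesses has no variety: the index is defined as 0 and flagged.

    Returns ``(mix, empty_flag)``.
    """
    counts = {c: 0 for c in BUSINESS_CATEGORIES}
    for p in businesses.points:
        if buffer.polygon.covers(p.geometry):
            counts[p.category] += 1
    n = sum(counts.values())
    if n == 0:
        return 0.0, True
    entropy = 0.0
    for c in counts.values():
        if c > 0:
            p_i = c / n
            entropy -= p_i * math.log(p_i)
    mix = entropy / math.log(len(BUSINESS_CATEGORIES))
    # clamp float fuzz; an exactly-equal mixture is exactly 1
    if abs(mix - 1.0) < 1e-12:
        mix = 1.0
    return mix, False


def compute_profile(
    net: StreetNetwork,
    home: Point,
    spaces: OpenSpaceLayer,
    businesses: BusinessLayer,
    tracts: TractLayer,
    radius: float = DEFAULT_RADIUS,
    offset: float = DEFAULT_BUFFER_OFFSET,
    cap_km: float = DEFAULT_DISTANCE_CAP / 1000.0,
    max_offset: float = DEFAULT_MAX_OFFSET,
    access: list | None = None,
) -> ExposureProfile:
    """Evaluate all eight metrics for one home location."""
    if access is None:
        access = openspace_access_points(net, spaces)
    buf = net.service_area(home, radius=radius, offset=offset, max_offset=max_offset)
    dens, tract_id, income = residential_density(home, tracts)
    mix, empty = land_use_mix(buf, businesses)
    return ExposureProfile(
        openspace_distance_km=nearest_openspace_distance(
            net, home, spaces, cap_km=cap_km, max_offset=max_offset, access=access
        ),
        openspace_count=openspace_count(buf, spaces),
        residential_density_per_km2=dens,
        traffic_density=traffic_density(buf),
        avg_speed_limit_mph=avg_speed_limit(buf),
        sidewalk_completeness=sidewalk_completeness(buf),
        intersection_density_per_km2=intersection_density(buf, net),
        land_use_mix=mix,
        tract_id=tract_id,
        tract_income_usd=income,
        land_use_mix_empty=empty,
    )


def compute_exposure_table(
    net: StreetNetwork,
    homes: pd.DataFrame,
    spaces: OpenSpaceLayer,
    businesses: BusinessLayer,
    tracts: TractLayer,
    radius: float = DEFAULT_RADIUS,
    offset: float = DEFAULT_BUFFER_OFFSET,
    cap_km: float = DEFAULT_DISTANCE_CAP / 1000.0,
    max_offset: float = DEFAULT_MAX_OFFSET,
) -> pd.DataFrame:
    """Exposure table for a frame of homes with columns ``x``, ``y``.

    Profiles are computed once per distinct ``(x, y)`` and broadcast, so
    cohorts sharing home locations pay the GIS cost only per location.
    Returns one row per input row, indexed like ``homes``, with the eight
    metric columns plus ``tract_id``, ``tract_income_usd`` and the
    empty-buffer land-use-mix flag.
    """
    if not {"x", "y"}.issubset(homes.columns):
        raise LayerError("homes frame must have 'x' and 'y' columns")
    unique = homes[["x", "y"]].drop_duplicates()
    access = openspace_access_points(net, spaces)
    cache: dict[tuple[float, float], dict] = {}
    for _, row in unique.iterrows():
        key = (float(row.x), float(row.y))
        prof = compute_profile(
            net, Point(key), spaces, businesses, tracts,
            radius=radius, offset=offset, cap_km=cap_km, max_offset=max_offset,
            access=access,
        )
        cache[key] = prof.as_dict()
    records = [
        cache[(float(r.x), float(r.y))] for r in homes.itertuples(index=False)
    ]
    out = pd.DataFrame.from_records(records, index=homes.index)
    cols = EXPOSURE_COLUMNS + ["tract_id", "tract_income_usd", "land_use_mix_empty"]
    return out[cols]


def exposure_ranges_ok(table: pd.DataFrame) -> bool:
    """Check the range invariants of every metric column."""
    t = table
    checks = [
        (t.openspace_distance_km >= 0).all() and (t.openspace_distance_km <= 15).all(),
        (t.openspace_count >= 0).all(),
        (t.residential_density_per_km2 >= 0).all(),
        (t.traffic_density >= 0).all(),
        (t.avg_speed_limit_mph > 0).all(),
        (t.sidewalk_completeness >= 0).all() and (t.sidewalk_completeness <= 2).all(),
        (t.intersection_density_per_km2 >= 0).all(),
        (t.land_use_mix >= 0).all() and (t.land_use_mix <= 1).all(),
    ]
    return bool(np.all(checks))
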