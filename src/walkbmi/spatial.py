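"""Planar street-network primitives.

A street network is a planar graph built from polyline road segments in a
projected metric CRS.  Segment endpoints lying within a snap tolerance are
welded into shared nodes, and graph edge weights equal geometric segment
lengths, so shortest paths are along-street ("network") distances in meters.

The service area of a home is the set of street-centerline portions
reachable within a network radius (default 800 m), and its line-based
buffer is the planar region within a fixed offset (default 50 m) of those
portions.  All exposure metrics downstream are evaluated on such buffers.

Coordinates are assumed to be planar meters throughout; no geographic
(lon/lat) math is performed.  A declared geographic CRS is rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
from shapely.geometry import LineString, Point
from shapely.ops import substring, unary_union
from shapely.strtree import STRtree

from .errors import LayerError, OffNetworkError

DEFAULT_SNAP_TOLERANCE = 0.5
DEFAULT_MAX_OFFSET = 500.0
DEFAULT_RADIUS = 800.0
DEFAULT_BUFFER_OFFSET = 50.0
DEFAULT_DISTANCE_CAP = 15_000.0

#: quadrant segments used when buffering reached centerlines; 32 keeps the
#: polygonal approximation of round caps within ~5e-4 of the true circle area
_BUFFER_QUAD_SEGS = 32

_GEOGRAPHIC_CRS_TOKENS = ("4326", "WGS84", "WGS 84", "CRS84", "NAD83", "4269")


@dataclass(frozen=True)
class StreetSegment:
    """One road segment with the per-segment attributes used by the
    walkability metrics.

    Parameters
    ----------
    segment_id : str
        Stable identifier.
    geometry : shapely.LineString
        Centerline in projected planar meters, >= 2 vertices.
    speed_limit : float
        Posted speed limit, mph, > 0.
    adt : float
        Average daily traffic, vehicles/day, >= 0.
    sidewalk_code : int
        0 = no sidewalks, 1 = sidewalk on one side, 2 = both sides.
    has_median : bool
        Whether the road has a median (such roads are excluded from the
        sidewalk-completeness score).
    pedestrian_accessible : bool
        Whether the segment belongs to the pedestrian street network
        (used for intersection detection).
    """

    segment_id: str
    geometry: LineString
    speed_limit: float
    adt: float
    sidewalk_code: int
    has_median: bool = False
    pedestrian_accessible: bool = True

    def __post_init__(self) -> None:
        if len(self.geometry.coords) < 2 or self.geometry.length <= 0:
            raise LayerError(
                f"segment {self.segment_id!r}: geometry must have >=2 vertices "
                "and positive length"
            )
        if self.sidewalk_code not in (0, 1, 2):
            raise LayerError(
                f"segment {self.segment_id!r}: sidewalk_code must be 0, 1 or 2"
            )
        if self.adt < 0:
            raise LayerError(f"segment {self.segment_id!r}: adt must be >= 0")
        if self.speed_limit <= 0:
            raise LayerError(
                f"segment {self.segment_id!r}: speed_limit must be > 0"
            )

    @property
    def length(self) -> float:
        return self.geometry.length


@dataclass(frozen=True)
class ProjectedPoint:
    """A point attached to the network by perpendicular projection."""

    edge: tuple[int, int, int]  # (u, v, key) with u at the geometry start
    t: float  # arc-length position along the edge geometry, meters
    offset: float  # perpendicular distance from the original point, meters
    point_on_line: Point


@dataclass(frozen=True)
class ReachedPortion:
    """A clipped piece of a segment centerline inside a service area."""

    segment: StreetSegment
    geometry: LineString

    @property
    def length(self) -> float:
        return self.geometry.length


@dataclass
class NetworkBuffer:
    """Line-based network buffer around an origin.

    ``reached`` holds the centerline portions within ``radius`` network
    meters of the origin (partial segments clipped at exactly the radius);
    ``polygon`` is the union of ``offset``-meter round-ended buffers around
    them, and ``area_km2`` its planar area.
    """

    origin: Point
    radius: float
    offset: float
    reached: list[ReachedPortion]
    polygon: object  # shapely Polygon or MultiPolygon
    area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.area_km2 = self.polygon.area / 1e6

    @property
    def reached_length(self) -> float:
        """Total reached centerline length, meters."""
        return sum(p.length for p in self.reached)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _weld_endpoints(
    endpoints: list[tuple[float, float]], tol: float
) -> list[int]:
    """Cluster endpoint coordinates lying within ``tol`` of each other.

    Returns, for each endpoint, the index of its cluster representative.
    Uses a spatial hash with cell size ``tol`` so only neighboring cells
    are compared.
    """
    uf = _UnionFind(len(endpoints))
    if tol <= 0:
        tol = 1e-12
    cells: dict[tuple[int, int], list[int]] = {}
    for i, (x, y) in enumerate(endpoints):
        cells.setdefault((math.floor(x / tol), math.floor(y / tol)), []).append(i)
    tol2 = tol * tol
    for (cx, cy), members in cells.items():
        neighborhood = list(members)
        for dx, dy in itertools.product((-1, 0, 1), repeat=2):
            if (dx, dy) == (0, 0):
                continue
            neighborhood.extend(cells.get((cx + dx, cy + dy), ()))
        for i in members:
            xi, yi = endpoints[i]
            for j in neighborhood:
                if j <= i:
                    continue
                xj, yj = endpoints[j]
                if (xi - xj) ** 2 + (yi - yj) ** 2 <= tol2:
                    uf.union(i, j)
    return [uf.find(i) for i in range(len(endpoints))]


class StreetNetwork:
    """Planar graph over a collection of :class:`StreetSegment`.

    Nodes are welded segment endpoints; each segment contributes one edge
    whose weight is its geometric length.  Parallel edges and self-loops
    are representable (``networkx.MultiGraph``).
    """

    def __init__(
        self,
        segments: list[StreetSegment],
        snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
        crs: str | None = None,
    ) -> None:
        if not segments:
            raise LayerError("cannot build a street network from zero segments")
        if crs is not None and any(
            tok in str(crs).upper() for tok in _GEOGRAPHIC_CRS_TOKENS
        ):
            raise LayerError(
                f"declared CRS {crs!r} looks geographic; supply geometry in a "
                "projected planar CRS in meters"
            )
        self.segments = list(segments)
        self.snap_tolerance = snap_tolerance

        endpoints: list[tuple[float, float]] = []
        for seg in self.segments:
            coords = list(seg.geometry.coords)
            endpoints.append(coords[0][:2])
            endpoints.append(coords[-1][:2])
        roots = _weld_endpoints(endpoints, snap_tolerance)

        node_of_root: dict[int, int] = {}
        self.graph = nx.MultiGraph()
        self._node_xy: dict[int, tuple[float, float]] = {}
        for idx, root in enumerate(roots):
            if root not in node_of_root:
                nid = len(node_of_root)
                node_of_root[root] = nid
                self._node_xy[nid] = endpoints[idx]
                self.graph.add_node(nid, xy=endpoints[idx])
        for k, seg in enumerate(self.segments):
            u = node_of_root[roots[2 * k]]
            v = node_of_root[roots[2 * k + 1]]
            # edge geometry is stored oriented from u (geometry start) to v
            self.graph.add_edge(
                u, v, length=seg.length, geom=seg.geometry, start=u, segment=seg
            )
        self._tree = STRtree([seg.geometry for seg in self.segments])
        self._seg_edge: list[tuple[int, int, int]] = []
        # recover the (u, v, key) of each segment in insertion order
        counters: dict[tuple[int, int], int] = {}
        for k, seg in enumerate(self.segments):
            u = node_of_root[roots[2 * k]]
            v = node_of_root[roots[2 * k + 1]]
            kk = counters.get((min(u, v), max(u, v)), 0)
            counters[(min(u, v), max(u, v))] = kk + 1
            self._seg_edge.append((u, v, kk))

    # -- basic accessors -------------------------------------------------

    @property
    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments)

    def node_point(self, node: int) -> Point:
        return Point(self._node_xy[node])

    # -- point attachment ------------------------------------------------

    def project(
        self, point: Point, max_offset: float = DEFAULT_MAX_OFFSET
    ) -> ProjectedPoint:
        """Attach ``point`` to the nearest segment by perpendicular projection.

        Raises :class:`OffNetworkError` if the nearest segment is farther
        than ``max_offset`` meters away.
        """
        idx = int(self._tree.nearest(point))
        geom = self.segments[idx].geometry
        offset = geom.distance(point)
        if offset > max_offset:
            raise OffNetworkError(
                f"point ({point.x:.1f}, {point.y:.1f}) is {offset:.1f} m from the "
                f"nearest street segment (max allowed {max_offset:.1f} m)"
            )
        t = geom.project(point)
        u, v, key = self._seg_edge[idx]
        data = self.graph[u][v][key]
        if data["start"] != u:  # stored orientation
            u, v = v, u
        return ProjectedPoint(
            edge=(u, v, key), t=t, offset=offset, point_on_line=geom.interpolate(t)
        )

    # -- virtual-node surgery ---------------------------------------------

    def _graph_with_points(
        self, points: list[ProjectedPoint]
    ) -> tuple[nx.MultiGraph, list]:
        """Copy the graph with each projected point inserted as a node,
        splitting its edge at the projection position.  Points sharing an
        edge are chained in arc-length order."""
        H = self.graph.copy()
        by_edge: dict[tuple[int, int, int], list[tuple[float, object]]] = {}
        names = []
        for i, p in enumerate(points):
            u, v, key = p.edge
            eu, ev = (u, v) if u <= v else (v, u)
            name = ("virtual", i)
            names.append(name)
            by_edge.setdefault((eu, ev, key), []).append((p.t, name, p))
        for (eu, ev, key), items in by_edge.items():
            data = H[eu][ev][key]
            geom, start, L = data["geom"], data["start"], data["length"]
            seg = data["segment"]
            end = ev if start == eu else eu
            items.sort(key=lambda it: it[0])
            H.remove_edge(eu, ev, key)
            prev_node, prev_t = start, 0.0
            for t, name, _p in items:
                H.add_node(name)
                H.add_edge(
                    prev_node,
                    name,
                    length=t - prev_t,
                    geom=substring(geom, prev_t, t),
                    start=prev_node,
                    segment=seg,
                )
                prev_node, prev_t = name, t
            H.add_edge(
                prev_node,
                end,
                length=L - prev_t,
                geom=substring(geom, prev_t, L),
                start=prev_node,
                segment=seg,
            )
        return H, names

    # -- core operations ---------------------------------------------------

    def network_distance(
        self,
        a: Point,
        b: Point,
        cap: float = DEFAULT_DISTANCE_CAP,
        max_offset: float = DEFAULT_MAX_OFFSET,
    ) -> float:
        """Shortest along-network distance between two points, meters.

        Both points are projected perpendicularly onto their nearest
        segment; the returned value is the shortest path between the two
        projection points plus the two perpendicular offsets, truncated at
        ``cap`` (points in different components are reported at ``cap``).
        """
        if cap <= 0:
            raise ValueError("cap must be > 0")
        pa = self.project(a, max_offset)
        pb = self.project(b, max_offset)
        H, (na, nb) = self._graph_with_points([pa, pb])
        try:
            d = nx.dijkstra_path_length(H, na, nb, weight="length")
        except nx.NetworkXNoPath:
            return cap
        return min(d + pa.offset + pb.offset, cap)

    def distances_from(
        self,
        point: Point,
        cap: float = DEFAULT_DISTANCE_CAP,
        max_offset: float = DEFAULT_MAX_OFFSET,
    ) -> tuple[ProjectedPoint, dict]:
        """Single-source network distances from a point to every node.

        Returns the point's projection and a dict of node -> distance in
        meters (nodes beyond ``cap`` absent).  Pair with
        :meth:`distance_to_projected` for one-to-many queries.
        """
        p = self.project(point, max_offset)
        H, (src,) = self._graph_with_points([p])
        dist = nx.single_source_dijkstra_path_length(
            H, src, cutoff=cap, weight="length"
        )
        return p, dist

    def distance_to_projected(
        self, source: ProjectedPoint, dist: dict, target: ProjectedPoint
    ) -> float:
        """Network distance to ``target`` given ``distances_from(source)``.

        Includes both perpendicular projection offsets; ``inf`` when the
        target is unreachable within the cap used for ``dist``.
        """
        u, v, key = target.edge
        L = self.graph[u][v][key]["length"]
        best = math.inf
        su, sv, skey = source.edge
        if (min(u, v), max(u, v), key) == (min(su, sv), max(su, sv), skey):
            best = abs(target.t - source.t)
        du = dist.get(u, math.inf)
        dv = dist.get(v, math.inf)
        best = min(best, du + target.t, dv + (L - target.t))
        return best + source.offset + target.offset

    def service_area(
        self,
        origin: Point,
        radius: float = DEFAULT_RADIUS,
        offset: float = DEFAULT_BUFFER_OFFSET,
        max_offset: float = DEFAULT_MAX_OFFSET,
    ) -> NetworkBuffer:
        """Line-based network buffer around ``origin``.

        Every centerline portion within ``radius`` network meters of the
        origin's projection is collected (partial segments clipped at
        exactly the radius), then buffered by ``offset`` meters with round
        joins and caps; the polygon is the union of those regions.
        """
        if radius <= 0 or offset <= 0:
            raise ValueError("radius and offset must be > 0")
        p = self.project(origin, max_offset)
        H, (src,) = self._graph_with_points([p])
        dist = nx.single_source_dijkstra_path_length(
            H, src, cutoff=radius, weight="length"
        )
        portions: list[ReachedPortion] = []
        for u, v, data in H.edges(data=True):
            L, geom, seg = data["length"], data["geom"], data["segment"]
            if L <= 0:
                continue
            start = data["start"]
            end = v if start == u else u
            du = dist.get(start, math.inf)
            dv = dist.get(end, math.inf)
            ru = min(max(radius - du, 0.0), L) if math.isfinite(du) else 0.0
            rv = min(max(radius - dv, 0.0), L) if math.isfinite(dv) else 0.0
            if ru <= 0 and rv <= 0:
                continue
            if ru + rv >= L:
                portions.append(ReachedPortion(seg, geom))
            else:
                if ru > 0:
                    portions.append(ReachedPortion(seg, substring(geom, 0.0, ru)))
                if rv > 0:
                    portions.append(ReachedPortion(seg, substring(geom, L - rv, L)))
        if not portions:
            raise OffNetworkError(
                "service area is empty: origin does not reach any centerline "
                "portion within the radius"
            )
        polygon = unary_union(
            [p_.geometry.buffer(offset, quad_segs=_BUFFER_QUAD_SEGS) for p_ in portions]
        )
        return NetworkBuffer(
            origin=origin, radius=radius, offset=offset, reached=portions,
            polygon=polygon,
        )

    def find_intersections(self, pedestrian_only: bool = False) -> list[Point]:
        """Nodes where three or more road segments come together.

        With ``pedestrian_only`` the incident-segment count is taken on the
        pedestrian street network (segments flagged pedestrian-accessible).
        """
        counts: dict[int, int] = {}
        for u, v, k in self._seg_edge:
            seg = self.graph[u][v][k]["segment"]
            if pedestrian_only and not seg.pedestrian_accessible:
                continue
            counts[u] = counts.get(u, 0) + 1
            counts[v] = counts.get(v, 0) + 1
        return [
            Point(self._node_xy[n]) for n, c in sorted(counts.items()) if c >= 3
        ]


def build_network(
    segments: list[StreetSegment],
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
    crs: str | None = None,
) -> StreetNetwork:
    """Build a :class:`StreetNetwork`, welding endpoints within ``snap_tolerance``."""
    return StreetNetwork(segments, snap_tolerance=snap_tolerance, crs=crs)
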