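"""GeoJSON layer containers and I/O.

Four vector layers drive the exposure engine:

* streets — LineString features with per-segment walkability attributes,
* open space — Polygon/Point features for public and private recreational
  open space (parks, playing fields, school fields),
* businesses — Point features in one of five categories used by the
  land-use-mix index,
* tracts — census-tract Polygons carrying median household income,
  housing-unit counts and land area.

All geometry is expected in one projected planar CRS in meters.  Files are
plain GeoJSON FeatureCollections; property names are part of the package's
public schema and documented in the README.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import LayerError
from .spatial import StreetSegment

#: the five business categories of the land-use-mix index
BUSINESS_CATEGORIES = (
    "food",
    "retail",
    "services",
    "cultural/educational",
    "physical activity",
)

STREET_PROPERTIES = (
    "segment_id",
    "speed_limit_mph",
    "adt",
    "sidewalk_code",
    "has_median",
    "pedestrian",
)


@dataclass(frozen=True)
class OpenSpaceFeature:
    feature_id: str
    geometry: BaseGeometry


@dataclass(frozen=True)
class OpenSpaceLayer:
    """Public and private recreational open space features."""

    features: tuple[OpenSpaceFeature, ...]

    def __post_init__(self) -> None:
        for f in self.features:
            if f.geometry.is_empty:
                raise LayerError(f"open space {f.feature_id!r}: empty geometry")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class BusinessPoint:
    geometry: BaseGeometry
    category: str

    def __post_init__(self) -> None:
        if self.category not in BUSINESS_CATEGORIES:
            raise LayerError(
                f"business category {self.category!r} not one of "
                f"{BUSINESS_CATEGORIES}"
            )


@dataclass(frozen=True)
class BusinessLayer:
    points: tuple[BusinessPoint, ...]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Tract:
    tract_id: str
    geometry: BaseGeometry
    median_income: float
    housing_units: float
    land_area_km2: float

    def __post_init__(self) -> None:
        if self.land_area_km2 <= 0:
            raise LayerError(f"tract {self.tract_id!r}: land_area_km2 must be > 0")
        if self.housing_units < 0:
            raise LayerError(f"tract {self.tract_id!r}: housing_units must be >= 0")


@dataclass(frozen=True)
class TractLayer:
    tracts: tuple[Tract, ...]

    def __len__(self) -> int:
        return len(self.tracts)


# ---------------------------------------------------------------------------
# GeoJSON round-trip


def _read_feature_collection(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise LayerError(f"layer file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise LayerError(f"{path}: not a GeoJSON FeatureCollection")
    return doc.get("features", [])


def _write_feature_collection(path: str | Path, features: list[dict]) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_streets(path: str | Path) -> list[StreetSegment]:
    segments = []
    for feat in _read_feature_collection(path):
        props = feat.get("properties", {})
        missing = [p for p in STREET_PROPERTIES if p not in props]
        if missing:
            raise LayerError(f"{path}: street feature missing properties {missing}")
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise LayerError(
                f"{path}: street geometry must be LineString, got {geom.geom_type}"
            )
        segments.append(
            StreetSegment(
                segment_id=str(props["segment_id"]),
                geometry=geom,
                speed_limit=float(props["speed_limit_mph"]),
                adt=float(props["adt"]),
                sidewalk_code=int(props["sidewalk_code"]),
                has_median=bool(props["has_median"]),
                pedestrian_accessible=bool(props["pedestrian"]),
            )
        )
    if not segments:
        raise LayerError(f"{path}: street layer is empty")
    return segments


def write_streets(path: str | Path, segments: list[StreetSegment]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(seg.geometry),
            "properties": {
                "segment_id": seg.segment_id,
                "speed_limit_mph": seg.speed_limit,
                "adt": seg.adt,
                "sidewalk_code": seg.sidewalk_code,
                "has_median": seg.has_median,
                "pedestrian": seg.pedestrian_accessible,
            },
        }
        for seg in segments
    ]
    _write_feature_collection(path, feats)


def read_openspace(path: str | Path) -> OpenSpaceLayer:
    feats = [
        OpenSpaceFeature(
            feature_id=str(f.get("properties", {}).get("id", i)),
            geometry=shape(f["geometry"]),
        )
        for i, f in enumerate(_read_feature_collection(path))
    ]
    return OpenSpaceLayer(features=tuple(feats))


def write_openspace(path: str | Path, layer: OpenSpaceLayer) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(f.geometry),
            "properties": {"id": f.feature_id},
        }
        for f in layer.features
    ]
    _write_feature_collection(path, feats)


def read_businesses(path: str | Path) -> BusinessLayer:
    pts = []
    for f in _read_feature_collection(path):
        props = f.get("properties", {})
        if "category" not in props:
            raise LayerError(f"{path}: business feature missing 'category'")
        pts.append(BusinessPoint(geometry=shape(f["geometry"]), category=props["category"]))
    return BusinessLayer(points=tuple(pts))


def write_businesses(path: str | Path, layer: BusinessLayer) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {"category": p.category},
        }
        for p in layer.points
    ]
    _write_feature_collection(path, feats)


def read_tracts(path: str | Path) -> TractLayer:
    tracts = []
    for f in _read_feature_collection(path):
        props = f.get("properties", {})
        missing = [
            p
            for p in ("tract_id", "median_income", "housing_units", "land_area_km2")
            if p not in props
        ]
        if missing:
            raise LayerError(f"{path}: tract feature missing properties {missing}")
        tracts.append(
            Tract(
                tract_id=str(props["tract_id"]),
                geometry=shape(f["geometry"]),
                median_income=float(props["median_income"]),
                housing_units=float(props["housing_units"]),
                land_area_km2=float(props["land_area_km2"]),
            )
        )
    return TractLayer(tracts=tuple(tracts))


def write_tracts(path: str | Path, layer: TractLayer) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(t.geometry),
            "properties": {
                "tract_id": t.tract_id,
                "median_income": t.median_income,
                "housing_units": t.housing_units,
                "land_area_km2": t.land_area_km2,
            },
        }
        for t in layer.tracts
    ]
    _write_feature_collection(path, feats)
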