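"""Metropolitan / nonmetropolitan classification from urban-area polygons.

Census urban-area polygons come in two kinds: *urbanized areas* (population
>= 50,000) and *urban clusters* (5,000 <= population < 50,000).  A post is
METRO iff its point falls inside at least one urbanized-area polygon; points
inside only urban clusters, or outside every urban polygon, are NONMETRO.
Boundary points count as inside (closed polygons).
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import Point, shape
from shapely.prepared import prep

METRO = "METRO"
NONMETRO = "NONMETRO"

URBANIZED = "urbanized"
URBAN_CLUSTER = "cluster"


class UrbanAreas:
    """Urban-area polygons tagged urbanized vs cluster."""

    def __init__(self, areas: list[tuple[str, object]]):
        for kind, _ in areas:
            if kind not in (URBANIZED, URBAN_CLUSTER):
                raise ValueError(f"unknown urban-area kind {kind!r}")
        self.areas = areas  # ordered (kind, shapely geometry)
        self._prepared = [(kind, prep(geom)) for kind, geom in areas]

    @classmethod
    def from_geojson(cls, path, kind_property: str = "kind") -> "UrbanAreas":
        gj = json.loads(Path(path).read_text(encoding="utf-8"))
        areas = []
        for feat in gj["features"]:
            geom = shape(feat["geometry"])
            if not geom.is_valid:
                raise ValueError("invalid urban-area polygon")
            areas.append((feat["properties"][kind_property], geom))
        return cls(areas)


def classify_metro(coords: tuple[float, float], areas: UrbanAreas) -> str:
    """METRO iff (lat, lon) is inside at least one urbanized-area polygon."""
    if coords is None:
        raise ValueError("coordinates required for metro classification")
    lat, lon = coords
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates {coords!r}")
    pt = Point(lon, lat)
    for kind, prepared in areas._prepared:
        if kind == URBANIZED and prepared.covers(pt):
            return METRO
    return NONMETRO
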