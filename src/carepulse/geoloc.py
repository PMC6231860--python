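"""Geolocation inference: free-text profile locations, GPS points, regions.

Posts rarely carry GPS coordinates, so a state is inferred from whichever
signal is available, GPS taking precedence:

* GPS coordinates -> point-in-polygon against state boundary polygons.
* Profile location string -> normalization, junk-library screening, then an
  offline gazetteer lookup.  The gazetteer returns an ordered candidate list
  (population-descending) and the FIRST candidate is taken; the gazetteer is
  a pluggable stand-in honoring the contract of an online geocoding service.

Outcomes form a partition: ``US_STATE`` (with the two-letter code, for the 50
states, DC, PR and VI), ``NON_US``, ``INSUFFICIENT`` (a location string was
present but junk or unresolvable), ``NONE`` (no location information at all).
States among the 50 + DC also carry their census region (NORTHEAST, MIDWEST,
SOUTH, WEST); PR and VI carry none.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from shapely.geometry import Point, shape
from shapely.prepared import prep

from ._data import data_path, read_word_list
from .ingest import TweetRecord

US_STATE = "US_STATE"
NON_US = "NON_US"
INSUFFICIENT = "INSUFFICIENT"
NONE = "NONE"

GPS = "GPS"
PROFILE = "PROFILE"

_REGIONS: dict[str, str] = {}


def census_region_map() -> dict[str, str]:
    """State code -> census region, for the 50 states + DC."""
    if not _REGIONS:
        with open(data_path("census_regions.csv"), encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                _REGIONS[row["state"]] = row["region"]
    return dict(_REGIONS)


def state_to_region(state: str) -> str:
    """Census region of a state; PR/VI and unknown codes raise KeyError."""
    region = census_region_map().get(state)
    if region is None:
        raise KeyError(f"no census region for {state!r}")
    return region


@dataclass(frozen=True)
class GeoInference:
    status: str
    state: Optional[str] = None
    region: Optional[str] = None
    coords: Optional[tuple[float, float]] = None
    source: Optional[str] = None


# ---------------------------------------------------------------------------
# Location-string normalization and junk screening

_EMOJI_SYMBOL_RE = re.compile(
    "["
    "\U0001F000-\U0001FAFF"  # emoji & pictographs
    "☀-➿"          # misc symbols, dingbats
    "←-⇿"          # arrows
    "⬀-⯿"          # more arrows/symbols
    "❤♥•©®™️"
    "]+"
)
_WS_RE = re.compile(r"\s+")


def normalize_location(raw: str) -> str:
    """Lowercase, trim, collapse whitespace, strip emoji/symbols."""
    s = _EMOJI_SYMBOL_RE.sub(" ", raw or "")
    s = s.lower()
    s = _WS_RE.sub(" ", s).strip()
    # tidy spaces around separators: "boston , ma" -> "boston, ma"
    s = re.sub(r"\s*,\s*", ", ", s)
    s = re.sub(r"\s*([|/])\s*", r"\1", s)
    return s.strip(" ,|/")


def split_segments(normalized: str) -> list[str]:
    """Ordered segments of a normalized string, split on commas/pipes/slashes."""
    return [seg.strip() for seg in re.split(r"[,|/]", normalized) if seg.strip()]


class JunkLocationLibrary:
    """Exact junk strings plus junk regex patterns, matched after normalization."""

    def __init__(self, exact: Sequence[str] = (), patterns: Sequence[str] = ()):
        self.exact = {normalize_location(e) for e in exact}
        self.patterns = [re.compile(p) for p in patterns]

    @classmethod
    def from_file(cls, path=None) -> "JunkLocationLibrary":
        """Load from a plain-text file (one entry per line; 'pattern:' prefix
        marks a regex; '#'-comments allowed). Defaults to the packaged library."""
        if path is None:
            path = data_path("junk_locations.txt")
        exact, patterns = [], []
        for line in read_word_list(path):
            if line.startswith("pattern:"):
                patterns.append(line[len("pattern:"):])
            else:
                exact.append(line)
        return cls(exact=exact, patterns=patterns)


def is_junk(normalized: str, lib: JunkLocationLibrary) -> bool:
    """True for junk strings; empty-after-normalization counts as junk."""
    if not normalized:
        return True
    if normalized in lib.exact:
        return True
    return any(p.search(normalized) for p in lib.patterns)


# ---------------------------------------------------------------------------
# Gazetteer


@dataclass(frozen=True)
class GazetteerCandidate:
    country: str            # ISO-ish country code, "US" for domestic
    state: Optional[str]    # two-letter code when country == "US"
    lat: float
    lon: float


class Gazetteer:
    """Offline place-string -> ordered candidate list lookup.

    Keys are normalized place strings; candidates are stored in rank order
    (the shipped fixtures rank by population, descending), and callers take
    the first candidate.
    """

    def __init__(self, entries: dict[str, list[GazetteerCandidate]]):
        self.entries = {normalize_location(k): list(v) for k, v in entries.items()}

    @classmethod
    def from_csv(cls, path) -> "Gazetteer":
        """Read place,candidate_rank,country,state,lat,lon rows."""
        rows = []
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rows.append(row)
        rows.sort(key=lambda r: (r["place"], int(r["candidate_rank"])))
        entries: dict[str, list[GazetteerCandidate]] = {}
        for row in rows:
            cand = GazetteerCandidate(
                country=row["country"],
                state=row["state"] or None,
                lat=float(row["lat"]),
                lon=float(row["lon"]),
            )
            entries.setdefault(row["place"], []).append(cand)
        return cls(entries)

    def lookup(self, normalized: str) -> list[GazetteerCandidate]:
        return list(self.entries.get(normalized, []))


def geocode(normalized: str, gaz: Gazetteer) -> list[GazetteerCandidate]:
    """Ordered candidates for a normalized, non-junk place string."""
    return gaz.lookup(normalized)


# ---------------------------------------------------------------------------
# State polygons


class StatePolygons:
    """State boundary polygons from a GeoJSON FeatureCollection.

    File order is preserved and acts as the documented tie-break for points
    on a shared boundary (first containing-or-touching polygon wins).
    GeoJSON coordinates are (lon, lat); the query API is (lat, lon).
    """

    def __init__(self, states: list[tuple[str, object]]):
        self.states = states  # ordered (code, shapely geometry)
        self._prepared = [(code, prep(geom)) for code, geom in states]

    @classmethod
    def from_geojson(cls, path, state_property: str = "state") -> "StatePolygons":
        gj = json.loads(Path(path).read_text(encoding="utf-8"))
        states = []
        seen = set()
        for feat in gj["features"]:
            code = feat["properties"][state_property]
            if code in seen:
                raise ValueError(f"duplicate state code {code!r}")
            seen.add(code)
            geom = shape(feat["geometry"])
            if not geom.is_valid:
                raise ValueError(f"invalid polygon for state {code!r}")
            states.append((code, geom))
        return cls(states)


def state_from_coords(coords: tuple[float, float], polys: StatePolygons) -> str:
    """State code containing (lat, lon); NON_US outside all polygons.

    Boundary points count as inside (``covers`` semantics).
    """
    lat, lon = coords
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates {coords!r}")
    pt = Point(lon, lat)
    for code, prepared in polys._prepared:
        if prepared.covers(pt):
            return code
    return NON_US


# ---------------------------------------------------------------------------
# Full inference


def _inference_from_candidate(cand: GazetteerCandidate) -> GeoInference:
    if cand.country == "US" and cand.state:
        return GeoInference(
            status=US_STATE,
            state=cand.state,
            region=census_region_map().get(cand.state),
            coords=(cand.lat, cand.lon),
            source=PROFILE,
        )
    return GeoInference(status=NON_US, coords=(cand.lat, cand.lon), source=PROFILE)


def infer(
    tweet: TweetRecord,
    gaz: Gazetteer,
    lib: JunkLocationLibrary,
    polys: StatePolygons,
) -> GeoInference:
    """Infer a location outcome for one post.

    GPS coordinates take precedence over the profile string.  A profile
    string is resolved whole-string first, then by its first segment.
    """
    if tweet.geo_coords is not None:
        state = state_from_coords(tweet.geo_coords, polys)
        if state == NON_US:
            return GeoInference(status=NON_US, coords=tweet.geo_coords, source=GPS)
        return GeoInference(
            status=US_STATE,
            state=state,
            region=census_region_map().get(state),
            coords=tweet.geo_coords,
            source=GPS,
        )
    raw = tweet.user_location
    if raw is None or not raw.strip():
        return GeoInference(status=NONE)
    normalized = normalize_location(raw)
    if is_junk(normalized, lib):
        return GeoInference(status=INSUFFICIENT)
    queries = [normalized]
    segments = split_segments(normalized)
    if segments and segments[0] != normalized:
        queries.append(segments[0])
    for q in queries:
        candidates = geocode(q, gaz)
        if candidates:
            return _inference_from_candidate(candidates[0])
    return GeoInference(status=INSUFFICIENT)
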