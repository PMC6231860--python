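import json

import pytest

from carepulse import geoloc, metro, sentiment, synth


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Generated geographic/lexicon fixture files, shared across the session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return synth.generate_fixtures(outdir)


@pytest.fixture(scope="session")
def gazetteer(fixture_paths):
    return geoloc.Gazetteer.from_csv(fixture_paths["gazetteer"])


@pytest.fixture(scope="session")
def junk_library(fixture_paths):
    return geoloc.JunkLocationLibrary.from_file(fixture_paths["junk"])


@pytest.fixture(scope="session")
def state_polygons(fixture_paths):
    return geoloc.StatePolygons.from_geojson(fixture_paths["states"])


@pytest.fixture(scope="session")
def urban_areas(fixture_paths):
    return metro.UrbanAreas.from_geojson(fixture_paths["urban"])


@pytest.fixture(scope="session")
def lexicon(fixture_paths):
    lex = sentiment.load_lexicon(fixture_paths["lexicon"])
    return sentiment.augment_emoji(lex, fixture_paths["emoji"])


@pytest.fixture(scope="session")
def state_rings(fixture_paths):
    """(state, outer ring) pairs for the ray-casting oracle."""
    gj = json.loads(fixture_paths["states"].read_text())
    return [
        (f["properties"]["state"], f["geometry"]["coordinates"][0])
        for f in gj["features"]
    ]


@pytest.fixture(scope="session")
def urban_rings(fixture_paths):
    gj = json.loads(fixture_paths["urban"].read_text())
    return [
        (f["properties"]["kind"], f["geometry"]["coordinates"][0])
        for f in gj["features"]
    ]
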