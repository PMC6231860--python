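"""End-to-end convenience runner used by the CLI and the acceptance script.

Chains structural filtering, geolocation, sentiment scoring, metro
classification and local-time conversion over a corpus, returning one tidy
DataFrame row per post that survives the structural filter.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import geoloc, metro, sentiment, temporal
from .ingest import FilterReport, TweetRecord, structural_filter


def run_pipeline(
    records: Sequence[TweetRecord],
    gaz: geoloc.Gazetteer,
    junk: geoloc.JunkLocationLibrary,
    polys: geoloc.StatePolygons,
    areas: metro.UrbanAreas,
    lex: sentiment.SentimentLexicon,
    tzmap: Optional[temporal.StateTimezoneMap] = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter, geolocate, score and classify a corpus.

    Columns: tweet_id, status, state, region, metro (True/False/None),
    score, polarity, local_hour, local_weekday (None where no state).
    """
    tzmap = tzmap or temporal.StateTimezoneMap.default()
    kept, report = structural_filter(records)
    rows = []
    for rec in kept:
        geo = geoloc.infer(rec, gaz, junk, polys)
        sent = sentiment.score_tweet(rec.text, lex)
        is_metro = local_hour = local_weekday = None
        if geo.status == geoloc.US_STATE:
            if geo.coords is not None:
                is_metro = metro.classify_metro(geo.coords, areas) == metro.METRO
            if geo.state in tzmap.mapping:
                local = temporal.to_local(rec.created_at_utc, geo.state, tzmap)
                local_hour, local_weekday = local.hour, local.weekday()
        rows.append({
            "tweet_id": rec.tweet_id,
            "status": geo.status,
            "state": geo.state,
            "region": geo.region,
            "metro": is_metro,
            "score": sent.score,
            "polarity": sent.polarity,
            "local_hour": local_hour,
            "local_weekday": local_weekday,
        })
    return pd.DataFrame(rows), report
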