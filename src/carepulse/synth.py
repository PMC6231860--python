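"""Synthetic labeled tweet corpora and geographic fixtures.

Real surveillance corpora of this kind are licensed and cannot ship, so the
generator emulates the statistical structure the analysis assumes and writes
the hidden truth to a sidecar, never into the main stream:

* a configurable relevant/irrelevant mix, with URL presence far more likely
  on irrelevant posts (odds multiplier, default 18);
* per-post sentiment targets drawn from a symmetric bimodal two-Gaussian
  mixture (defaults solve pooled mean -0.06, SD 0.509); post text is then
  composed from a keyword-class template sentence (compound 0) plus a
  sentence of plain lexicon words whose valence sum lands the scorer on the
  target, closing the loop between generator and scorer without inverting
  the normalization analytically;
* a toy geography of 8 rectangular states across the 4 census regions, each
  holding one urbanized area and one urban cluster, with a matching
  gazetteer, junk/missing/non-US profile strings, and GPS coordinates;
* diurnal posting activity with a night-time boost on negative polarity that
  is re-balanced during the day so the marginal sentiment mixture is
  preserved.

``generate_fixtures`` writes the mutually-consistent fixture files
(gazetteer, state and urban-area GeoJSON, lexicons, populations, timezone
map, ruleset) and asserts their consistency.
"""

from __future__ import annotations

import itertools
import json
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
from scipy.optimize import brentq

from ._data import data_path
from .ingest import TweetRecord
from .sentiment import load_lexicon

# ---------------------------------------------------------------------------
# Toy geography: 8 rectangular states across the 4 census regions.
# Rect = (lon_min, lat_min, lon_max, lat_max); coordinates are fictitious.

STATE_RECTS: dict[str, tuple[float, float, float, float]] = {
    "WA": (-125.0, 39.0, -118.0, 46.0),
    "CA": (-125.0, 31.0, -118.0, 38.0),
    "IL": (-116.0, 39.0, -109.0, 46.0),
    "OH": (-116.0, 31.0, -109.0, 38.0),
    "TX": (-107.0, 39.0, -100.0, 46.0),
    "GA": (-107.0, 31.0, -100.0, 38.0),
    "NY": (-98.0, 39.0, -91.0, 46.0),
    "MA": (-98.0, 31.0, -91.0, 38.0),
}

TOY_STATES = list(STATE_RECTS)

STATE_POPULATIONS = {
    "WA": 7_000_000, "CA": 39_000_000, "IL": 12_800_000, "OH": 11_700_000,
    "TX": 27_000_000, "GA": 10_200_000, "NY": 19_800_000, "MA": 6_800_000,
}

CITY_NAMES = {
    "WA": "cedarport", "CA": "goldvale", "IL": "prairieton", "OH": "lakemont",
    "TX": "mesquita", "GA": "peachford", "NY": "harborview", "MA": "baymeadow",
}

NON_US_PLACES = {          # place -> (country, lat, lon)
    "paris, france": ("FR", 48.86, 2.35),
    "toronto": ("CA", 43.65, -79.38),
    "london": ("GB", 51.51, -0.13),
    "sydney": ("AU", -33.87, 151.21),
}

JUNK_STRINGS = ["in your heart", "with aliens", "under your bed", "planet earth",
                "the internet", "nowhere"]


def urbanized_rect(state: str) -> tuple[float, float, float, float]:
    """The state's urbanized-area rectangle (its single metro)."""
    x0, y0, _, _ = STATE_RECTS[state]
    return (x0 + 1.0, y0 + 1.0, x0 + 2.5, y0 + 2.5)


def cluster_rect(state: str) -> tuple[float, float, float, float]:
    """The state's urban-cluster rectangle (a small town)."""
    x0, y0, _, _ = STATE_RECTS[state]
    return (x0 + 4.5, y0 + 4.5, x0 + 5.5, y0 + 5.5)


def metro_city_point(state: str) -> tuple[float, float]:
    x0, y0, x1, y1 = urbanized_rect(state)
    return ((y0 + y1) / 2, (x0 + x1) / 2)     # (lat, lon)


def rural_town_point(state: str) -> tuple[float, float]:
    x0, y0, _, _ = STATE_RECTS[state]
    return (y0 + 0.4, x0 + 0.4)


def _rect_feature(rect, props) -> dict:
    x0, y0, x1, y1 = rect
    return {
        "type": "Feature",
        "properties": props,
        "geometry": {
            "type": "Polygon",
            "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
        },
    }


# ---------------------------------------------------------------------------
# Generator configuration


@dataclass(frozen=True)
class SentimentMixture:
    """Two-Gaussian mixture over per-post sentiment targets."""

    neg_mean: float = -0.50
    neg_sd: float = 0.219
    pos_mean: float = 0.42
    pos_sd: float = 0.219
    neg_weight: float = 0.522

    @property
    def mean(self) -> float:
        return self.neg_weight * self.neg_mean + (1 - self.neg_weight) * self.pos_mean

    @property
    def sd(self) -> float:
        w = self.neg_weight
        second = (w * (self.neg_sd ** 2 + self.neg_mean ** 2)
                  + (1 - w) * (self.pos_sd ** 2 + self.pos_mean ** 2))
        return float(np.sqrt(second - self.mean ** 2))


@dataclass(frozen=True)
class GeneratorConfig:
    n_tweets: int = 20_000
    seed: int = 0
    relevance_rate: float = 0.101
    url_rate: float = 0.6612
    url_irrelevance_odds: float = 18.0
    retweet_rate: float = 0.40
    duplicate_rate: float = 0.01
    sentiment_mixture: SentimentMixture = field(default_factory=SentimentMixture)
    state_weights: Optional[dict[str, float]] = None
    metro_fraction: float = 0.69
    night_negative_boost: float = 1.35
    gps_rate: float = 0.03
    junk_location_rate: float = 0.145
    missing_location_rate: float = 0.35
    non_us_rate: float = 0.19
    plant_token: Optional[str] = None
    start: str = "2013-02-01"
    end: str = "2017-02-28"

    def validate(self) -> None:
        probs = {
            "relevance_rate": self.relevance_rate, "url_rate": self.url_rate,
            "retweet_rate": self.retweet_rate, "duplicate_rate": self.duplicate_rate,
            "metro_fraction": self.metro_fraction, "gps_rate": self.gps_rate,
            "junk_location_rate": self.junk_location_rate,
            "missing_location_rate": self.missing_location_rate,
            "non_us_rate": self.non_us_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.url_irrelevance_odds <= 0 or self.night_negative_boost <= 0:
            raise ValueError("odds multipliers must be positive")
        if self.n_tweets <= 0:
            raise ValueError("n_tweets must be positive")
        rest = 1.0 - (self.gps_rate + self.junk_location_rate
                      + self.missing_location_rate + self.non_us_rate)
        if rest < 0:
            raise ValueError("location-mode rates exceed 1")
        if self.state_weights:
            unknown = set(self.state_weights) - set(TOY_STATES)
            if unknown:
                raise ValueError(f"unknown toy states {unknown}")


# ---------------------------------------------------------------------------
# Text composition

RELEVANT_TEMPLATES = [
    "just got discharged from the hospital after my surgery.",
    "sitting in the waiting room for my checkup at the clinic.",
    "the nurse came by to monitor my recovery this morning.",
    "my doctor changed my medication dose again.",
    "been feeling sick all week and the er visit took hours.",
    "my insurance denied the bill for my operation.",
    "grandma is still in the ward with her heart condition.",
    "the dentist said my tooth needs another procedure.",
    "taking antibiotics for this illness my physician prescribed.",
    "dad had his transplant and the surgeon checked on him.",
]

IRRELEVANT_TEMPLATES = [
    "new article covers trends in hospital billing this quarter.",
    "webinar on insurance coverage options opens for registration.",
    "five tips to cure boredom on a rainy weekend.",
    "study finds screen time links to posture pain in offices.",
    "brand announces sick deals on sneakers and streetwear.",
    "health startup launches medication reminder app for clinics.",
    "conference keynote explores monitor design for gamers.",
    "local team wins in the dying seconds at the stadium.",
    "podcast episode reviews the ill fated expedition documentary.",
    "career care workshop offers resume reviews downtown.",
]

#: local hours treated as night for the negativity boost (8 pm - 10 am).
NIGHT_HOURS = frozenset(list(range(20, 24)) + list(range(0, 10)))

#: relative posting activity by local hour (day-heavy, evening shoulder).
HOUR_ACTIVITY = np.array(
    [0.35, 0.3, 0.25, 0.2, 0.2, 0.25, 0.4, 0.6, 0.8, 1.0,
     1.4, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5,
     1.4, 1.2, 0.8, 0.5]
)

_ALPHA = 15.0
_COMPOSE_CACHE: Optional[tuple] = None


def _compose_table():
    """Sorted valence sums of all 1..3-word combos of the mini-lexicon."""
    global _COMPOSE_CACHE
    if _COMPOSE_CACHE is None:
        lex = load_lexicon()
        words = sorted(lex.words)
        vals = np.array([lex.words[w] for w in words])
        combos: list[tuple[int, ...]] = []
        for k in (1, 2, 3):
            combos.extend(itertools.combinations(range(len(words)), k))
        sums = np.array([vals[list(c)].sum() for c in combos])
        order = np.argsort(sums)
        _COMPOSE_CACHE = (words, [combos[i] for i in order], sums[order])
    return _COMPOSE_CACHE


def compose_sentiment_words(target_compound: float, rng: np.random.Generator) -> list[str]:
    """Plain lexicon words whose valence sum scores near the target compound."""
    words, combos, sums = _compose_table()
    c = float(np.clip(target_compound, -0.92, 0.92))
    x = c * np.sqrt(_ALPHA / (1.0 - c * c))
    i = int(np.searchsorted(sums, x))
    best = min(
        (j for j in (i - 1, i) if 0 <= j < len(sums)),
        key=lambda j: abs(sums[j] - x),
    )
    chosen = [words[k] for k in combos[best]]
    rng.shuffle(chosen)
    return chosen


def _solve_url_odds(cfg: GeneratorConfig) -> tuple[float, float]:
    """P(url|relevant), P(url|irrelevant) hitting the marginal url_rate."""
    r, m, k = cfg.relevance_rate, cfg.url_rate, cfg.url_irrelevance_odds
    if m in (0.0, 1.0):
        return m, m

    def marginal(o):
        return r * o / (1 + o) + (1 - r) * k * o / (1 + k * o) - m

    o = brentq(marginal, 1e-12, 1e12)
    return o / (1 + o), k * o / (1 + k * o)


def _solve_night_weights(cfg: GeneratorConfig) -> tuple[float, float]:
    """Night/day negative-component weights preserving the marginal mixture.

    Night posts get ``night_negative_boost`` times the day odds of drawing the
    negative component; the day weight is solved so the activity-weighted
    marginal equals the configured mixture weight.
    """
    w = cfg.sentiment_mixture.neg_weight
    b = cfg.night_negative_boost
    act = HOUR_ACTIVITY / HOUR_ACTIVITY.sum()
    f_night = float(sum(act[h] for h in NIGHT_HOURS))
    if b == 1.0:
        return w, w

    def marginal(o_day):
        w_day = o_day / (1 + o_day)
        w_night = b * o_day / (1 + b * o_day)
        return f_night * w_night + (1 - f_night) * w_day - w

    o = brentq(marginal, 1e-12, 1e12)
    return b * o / (1 + b * o), o / (1 + o)


# ---------------------------------------------------------------------------
# Corpus generation


def generate_corpus(config: GeneratorConfig) -> tuple[list[TweetRecord], list[dict]]:
    """Generate a labeled corpus; returns (records, truth sidecar rows).

    Truth rows carry the hidden labels (relevance, target and achieved
    sentiment, true state, metro flag, location mode, local hour) and are
    never written into the main stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_tweets
    mix = config.sentiment_mixture

    states = TOY_STATES
    if config.state_weights:
        w = np.array([config.state_weights.get(s, 0.0) for s in states], dtype=float)
    else:
        w = np.ones(len(states))
    w = w / w.sum()

    relevant = rng.random(n) < config.relevance_rate
    p_url_rel, p_url_irr = _solve_url_odds(config)
    has_url = rng.random(n) < np.where(relevant, p_url_rel, p_url_irr)
    is_retweet = rng.random(n) < config.retweet_rate
    state_idx = rng.choice(len(states), size=n, p=w)
    metro = rng.random(n) < config.metro_fraction

    mode_p = [config.gps_rate, config.missing_location_rate,
              config.junk_location_rate, config.non_us_rate]
    mode_p.append(max(0.0, 1.0 - sum(mode_p)))
    modes = rng.choice(5, size=n, p=np.array(mode_p) / sum(mode_p))
    MODE_GPS, MODE_MISSING, MODE_JUNK, MODE_NONUS, MODE_PROFILE = range(5)

    start = datetime.fromisoformat(config.start)
    end = datetime.fromisoformat(config.end)
    n_days = (end - start).days + 1
    days = rng.integers(0, n_days, size=n)
    hours = rng.choice(24, size=n, p=HOUR_ACTIVITY / HOUR_ACTIVITY.sum())
    minutes = rng.integers(0, 60, size=n)
    seconds = rng.integers(0, 60, size=n)

    w_night, w_day = _solve_night_weights(config)
    is_night = np.isin(hours, list(NIGHT_HOURS))
    neg_comp = rng.random(n) < np.where(is_night, w_night, w_day)
    targets = np.where(
        neg_comp,
        rng.normal(mix.neg_mean, mix.neg_sd, size=n),
        rng.normal(mix.pos_mean, mix.pos_sd, size=n),
    )
    targets = np.clip(targets, -0.92, 0.92)

    from .temporal import StateTimezoneMap  # cycle-free local import
    zones = {s: ZoneInfo(tz) for s, tz in StateTimezoneMap.default().mapping.items()
             if s in STATE_RECTS}

    records: list[TweetRecord] = []
    truth: list[dict] = []
    for i in range(n):
        st = states[state_idx[i]]
        local = datetime(start.year, start.month, start.day,
                         int(hours[i]), int(minutes[i]), int(seconds[i]),
                         tzinfo=zones[st]) + timedelta(days=int(days[i]))
        ts_utc = local.astimezone(timezone.utc)

        template_pool = RELEVANT_TEMPLATES if relevant[i] else IRRELEVANT_TEMPLATES
        keyword_sentence = template_pool[int(rng.integers(len(template_pool)))]
        if relevant[i] and config.plant_token:
            keyword_sentence = f"{config.plant_token} {keyword_sentence}"
        senti_words = compose_sentiment_words(float(targets[i]), rng)
        text = f"{keyword_sentence} {' '.join(senti_words)}."
        if has_url[i]:
            tag = "".join(rng.choice(list("abcdefghij0123456789"), size=8))
            text += f" http://t.co/{tag}"

        coords = None
        location: Optional[str] = None
        mode = int(modes[i])
        if mode == MODE_GPS:
            coords = _sample_point(st, bool(metro[i]), rng)
        elif mode == MODE_JUNK:
            location = JUNK_STRINGS[int(rng.integers(len(JUNK_STRINGS)))]
        elif mode == MODE_NONUS:
            location = list(NON_US_PLACES)[int(rng.integers(len(NON_US_PLACES)))]
        elif mode == MODE_PROFILE:
            name = CITY_NAMES[st]
            place = f"{name} city, {st.lower()}" if metro[i] else f"{name} falls, {st.lower()}"
            location = place.title() if rng.random() < 0.5 else place
        # MODE_MISSING leaves location None

        records.append(TweetRecord(
            tweet_id=f"t{i:08d}", text=text, created_at_utc=ts_utc,
            user_location=location, geo_coords=coords,
            is_retweet=bool(is_retweet[i]), has_url=bool(has_url[i]),
        ))
        truth.append({
            "tweet_id": f"t{i:08d}",
            "relevant": bool(relevant[i]),
            "target_score": float(targets[i]),
            "state": st,
            "metro": bool(metro[i]),
            "location_mode": ["gps", "missing", "junk", "non_us", "profile"][mode],
            "local_hour": int(hours[i]),
            "is_retweet": bool(is_retweet[i]),
            "has_url": bool(has_url[i]),
        })

    if config.duplicate_rate > 0 and records:
        n_dup = int(round(config.duplicate_rate * n))
        for j in rng.integers(0, len(records), size=n_dup):
            records.append(records[int(j)])
    return records, truth


def _sample_point(state: str, is_metro: bool, rng: np.random.Generator) -> tuple[float, float]:
    """(lat, lon) inside the state consistent with its metro flag."""
    if is_metro:
        x0, y0, x1, y1 = urbanized_rect(state)
        return (float(rng.uniform(y0, y1)), float(rng.uniform(x0, x1)))
    if rng.random() < 0.3:
        x0, y0, x1, y1 = cluster_rect(state)
        return (float(rng.uniform(y0, y1)), float(rng.uniform(x0, x1)))
    sx0, sy0, sx1, sy1 = STATE_RECTS[state]
    ux0, uy0, ux1, uy1 = urbanized_rect(state)
    cx0, cy0, cx1, cy1 = cluster_rect(state)
    while True:  # rejection sampling; urban rects cover <6% of the state
        lon, lat = rng.uniform(sx0, sx1), rng.uniform(sy0, sy1)
        in_urb = ux0 <= lon <= ux1 and uy0 <= lat <= uy1
        in_clu = cx0 <= lon <= cx1 and cy0 <= lat <= cy1
        if not in_urb and not in_clu:
            return (float(lat), float(lon))


def write_truth(truth: Sequence[dict], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for row in truth:
            fh.write(json.dumps(row) + "\n")


# ---------------------------------------------------------------------------
# Fixtures


def generate_fixtures(outdir) -> dict[str, Path]:
    """Write the mutually-consistent fixture files and self-check them.

    Returns a name -> path mapping: states, urban, gazetteer, junk, lexicon,
    emoji, populations, timezones, rules.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    states_gj = {
        "type": "FeatureCollection",
        "features": [_rect_feature(STATE_RECTS[s], {"state": s}) for s in TOY_STATES],
    }
    paths["states"] = outdir / "states.geojson"
    paths["states"].write_text(json.dumps(states_gj), encoding="utf-8")

    urban_feats = []
    for s in TOY_STATES:
        urban_feats.append(_rect_feature(urbanized_rect(s), {"kind": "urbanized", "state": s}))
        urban_feats.append(_rect_feature(cluster_rect(s), {"kind": "cluster", "state": s}))
    paths["urban"] = outdir / "urban.geojson"
    paths["urban"].write_text(
        json.dumps({"type": "FeatureCollection", "features": urban_feats}), encoding="utf-8"
    )

    rows = ["place,candidate_rank,country,state,lat,lon"]
    for s in TOY_STATES:
        name = CITY_NAMES[s]
        mlat, mlon = metro_city_point(s)
        rlat, rlon = rural_town_point(s)
        rows.append(f'"{name} city, {s.lower()}",1,US,{s},{mlat},{mlon}')
        rows.append(f"{name} city,1,US,{s},{mlat},{mlon}")
        rows.append(f'"{name} falls, {s.lower()}",1,US,{s},{rlat},{rlon}')
        rows.append(f"{name} falls,1,US,{s},{rlat},{rlon}")
    # a deliberately ambiguous place: candidates ranked by population
    for rank, s in enumerate(["IL", "MA", "OH"], start=1):
        mlat, mlon = metro_city_point(s)
        rows.append(f"springfield,{rank},US,{s},{mlat},{mlon}")
    for place, (country, lat, lon) in NON_US_PLACES.items():
        rows.append(f'"{place}",1,{country},,{lat},{lon}')
    paths["gazetteer"] = outdir / "gazetteer.csv"
    paths["gazetteer"].write_text("\n".join(rows) + "\n", encoding="utf-8")

    for name, src in [
        ("junk", "junk_locations.txt"), ("lexicon", "mini_lexicon.csv"),
        ("emoji", "emoji_lexicon.csv"), ("timezones", "state_timezones.csv"),
        ("rules", "default_rules.yaml"),
    ]:
        dst = outdir / src
        shutil.copyfile(data_path(src), dst)
        paths[name] = dst

    pop_rows = ["state,population"] + [
        f"{s},{STATE_POPULATIONS[s]}" for s in TOY_STATES
    ]
    paths["populations"] = outdir / "populations.csv"
    paths["populations"].write_text("\n".join(pop_rows) + "\n", encoding="utf-8")

    _self_check(paths)
    return paths


def _self_check(paths: dict[str, Path]) -> None:
    """Assert fixture consistency: gazetteer points round-trip their state,
    urbanized rectangles sit inside their state, populations are positive."""
    from .geoloc import Gazetteer, StatePolygons, state_from_coords
    from .metro import METRO, UrbanAreas, classify_metro

    polys = StatePolygons.from_geojson(paths["states"])
    areas = UrbanAreas.from_geojson(paths["urban"])
    gaz = Gazetteer.from_csv(paths["gazetteer"])
    for place, cands in gaz.entries.items():
        for cand in cands:
            if cand.country == "US":
                assert state_from_coords((cand.lat, cand.lon), polys) == cand.state, place
    for s in TOY_STATES:
        assert state_from_coords(metro_city_point(s), polys) == s
        assert classify_metro(metro_city_point(s), areas) == METRO
        assert STATE_POPULATIONS[s] > 0
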