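"""Corpus ingestion: reading post streams, keyword rules, structural filters.

A surveillance corpus starts life as a stream of JSON Lines records, one post
per line.  Ingestion (1) parses the stream into :class:`TweetRecord` objects,
(2) applies a keyword ruleset that decides whether a post is a candidate for
the patient-experience corpus at all, and (3) applies the structural filters
used throughout the analysis: reposts (retweets) are dropped, posts carrying a
URL are dropped (link-bearing posts are overwhelmingly promotional/news
content rather than first-person experience), and duplicate ids are dropped,
first occurrence winning.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import yaml

from ._data import data_path

logger = logging.getLogger(__name__)

#: scheme-based URL detection plus bare "www." prefixes; t.co short links
#: carry a scheme in practice and match the first alternative.
URL_RE = re.compile(r"(?:https?://\S+|\bwww\.\S+)", re.IGNORECASE)

#: default mapping from TweetRecord field -> JSON key.
DEFAULT_FIELD_MAP: Mapping[str, str] = {
    "tweet_id": "id",
    "text": "text",
    "created_at_utc": "timestamp",
    "user_location": "user_location",
    "geo_coords": "geo_coords",
    "is_retweet": "is_retweet",
    "has_url": "has_url",
}


@dataclass(frozen=True)
class TweetRecord:
    """One social post."""

    tweet_id: str
    text: str
    created_at_utc: datetime
    user_location: Optional[str] = None
    geo_coords: Optional[tuple[float, float]] = None  # (lat, lon), WGS84
    is_retweet: bool = False
    has_url: bool = False

    def __post_init__(self):
        if self.geo_coords is not None:
            lat, lon = self.geo_coords
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"coordinates out of range: {self.geo_coords}")


def _parse_timestamp(value) -> datetime:
    if isinstance(value, (int, float)):
        return datetime.fromtimestamp(value, tz=timezone.utc)
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def record_from_json(obj: Mapping, field_map: Mapping[str, str] = DEFAULT_FIELD_MAP) -> TweetRecord:
    """Build a TweetRecord from one decoded JSON object.

    ``has_url`` is derived from the text by URL-pattern detection when the
    input does not carry the field explicitly.
    """
    fm = field_map
    text = str(obj[fm["text"]])
    coords = obj.get(fm["geo_coords"])
    if coords is not None:
        coords = (float(coords[0]), float(coords[1]))
    has_url = obj.get(fm["has_url"])
    if has_url is None:
        has_url = bool(URL_RE.search(text))
    loc = obj.get(fm["user_location"])
    return TweetRecord(
        tweet_id=str(obj[fm["tweet_id"]]),
        text=text,
        created_at_utc=_parse_timestamp(obj[fm["created_at_utc"]]),
        user_location=None if loc is None else str(loc),
        geo_coords=coords,
        is_retweet=bool(obj.get(fm["is_retweet"], False)),
        has_url=bool(has_url),
    )


@dataclass
class CorpusReadResult:
    records: list[TweetRecord]
    n_malformed: int = 0


def read_corpus(path, field_map: Mapping[str, str] = DEFAULT_FIELD_MAP) -> CorpusReadResult:
    """Read a JSON Lines corpus; malformed lines are counted and skipped."""
    path = Path(path)
    records: list[TweetRecord] = []
    n_malformed = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(record_from_json(json.loads(line), field_map))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                n_malformed += 1
                logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
    return CorpusReadResult(records=records, n_malformed=n_malformed)


def write_corpus(records: Iterable[TweetRecord], path) -> None:
    """Write records as JSON Lines (inverse of :func:`read_corpus`)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "id": r.tweet_id,
                "text": r.text,
                "timestamp": r.created_at_utc.isoformat(),
                "is_retweet": r.is_retweet,
                "has_url": r.has_url,
            }
            if r.user_location is not None:
                obj["user_location"] = r.user_location
            if r.geo_coords is not None:
                obj["geo_coords"] = list(r.geo_coords)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Keyword ruleset


class KeywordRuleset:
    """Keyword classes plus boolean rules over them.

    Keywords are matched case-insensitively on word boundaries.  Classes
    listed in ``prefix_classes`` additionally match keywords as word prefixes
    ("recover" then also hits "recovery").  A rule is a conjunction of class
    names; the ruleset fires when at least one rule has all its classes
    matched (disjunction of conjunctions).
    """

    def __init__(
        self,
        classes: Mapping[str, Sequence[str]],
        rules: Optional[Sequence[Sequence[str]]] = None,
        prefix_classes: Sequence[str] = (),
    ):
        self.classes = {name: list(kws) for name, kws in classes.items()}
        if rules is None:
            rules = [[name] for name in self.classes]
        self.rules = [list(rule) for rule in rules]
        self.prefix_classes = set(prefix_classes)
        for rule in self.rules:
            for cls in rule:
                if cls not in self.classes:
                    raise ValueError(f"rule references undeclared class {cls!r}")
        for cls in self.prefix_classes:
            if cls not in self.classes:
                raise ValueError(f"prefix_classes references undeclared class {cls!r}")
        self._patterns = {
            name: self._compile(kws, prefix=name in self.prefix_classes)
            for name, kws in self.classes.items()
        }

    @staticmethod
    def _compile(keywords: Sequence[str], prefix: bool) -> re.Pattern:
        alts = []
        for kw in keywords:
            esc = re.escape(kw.lower()).replace(r"\ ", r"\s+")
            alts.append(esc + (r"\w*" if prefix else ""))
        body = "|".join(sorted(alts, key=len, reverse=True))
        return re.compile(r"(?<!\w)(?:%s)(?!\w)" % body, re.IGNORECASE)

    @classmethod
    def from_yaml(cls, path=None) -> "KeywordRuleset":
        """Load a ruleset config; defaults to the packaged ruleset."""
        if path is None:
            path = data_path("default_rules.yaml")
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            classes=cfg["classes"],
            rules=cfg.get("rules"),
            prefix_classes=cfg.get("prefix_classes") or (),
        )


def match_keywords(text: str, ruleset: KeywordRuleset) -> set[str]:
    """Names of every keyword class with at least one hit in ``text``."""
    if not text:
        return set()
    return {name for name, pat in ruleset._patterns.items() if pat.search(text)}


def rule_fires(matched_classes: set[str], ruleset: KeywordRuleset) -> bool:
    """True iff at least one rule is fully satisfied (post enters the corpus)."""
    return any(all(cls in matched_classes for cls in rule) for rule in ruleset.rules)


# ---------------------------------------------------------------------------
# Structural filter


@dataclass
class FilterReport:
    n_input: int = 0
    n_retweet: int = 0
    n_url: int = 0
    n_duplicate: int = 0
    n_kept: int = 0

    @property
    def removed(self) -> dict:
        return {"retweet": self.n_retweet, "url": self.n_url, "duplicate": self.n_duplicate}


def structural_filter(records: Iterable[TweetRecord]) -> tuple[list[TweetRecord], FilterReport]:
    """Drop retweets, URL-bearing posts and duplicate ids (first wins).

    Removal reasons are counted in precedence order retweet > url > duplicate,
    so each dropped record is counted exactly once and
    ``n_input == n_kept + sum(removed)``.
    """
    report = FilterReport()
    seen: set[str] = set()
    kept: list[TweetRecord] = []
    for rec in records:
        report.n_input += 1
        if rec.is_retweet:
            report.n_retweet += 1
        elif rec.has_url:
            report.n_url += 1
        elif rec.tweet_id in seen:
            report.n_duplicate += 1
        else:
            seen.add(rec.tweet_id)
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def keyword_filter(
    records: Iterable[TweetRecord], ruleset: KeywordRuleset
) -> Iterator[TweetRecord]:
    """Yield only records for which the ruleset fires."""
    for rec in records:
        if rule_fires(match_keywords(rec.text, ruleset), ruleset):
            yield rec
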