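"""Lexicon-and-rule sentiment scoring with emoji augmentation.

Each sentence of a post gets a *compound* score: signed word valences are
summed, adjusted by a small set of contextual rules, and squashed into
[-1, 1] by x -> x / sqrt(x^2 + alpha).  The per-post score is the mean of the
*nonzero* sentence compounds (a sentence containing no lexicon term is
uninformative, not neutral evidence).  Posts are classed POSITIVE when the
score is >= +0.3, NEGATIVE when <= -0.3, NEUTRAL otherwise.

Implemented rule subset: negation within a three-token window (scales the
valence by -0.74), booster words (shift by +-0.293 toward the valence sign,
damped with distance), ALL-CAPS emphasis, exclamation-mark emphasis (up to
three "!"), and up-weighting of the clause after "but".  The idiom and
special-case tables of the full lexicon method are out of scope.  All rule
constants live in :class:`RuleConfig`.
"""

from __future__ import annotations

import csv
import logging
import re
import string
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Optional, Sequence

from ._data import data_path

logger = logging.getLogger(__name__)

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
NEUTRAL = "NEUTRAL"

#: polarity thresholds, inclusive on both sides.
POLARITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class RuleConfig:
    """All contextual-rule constants in one place."""

    negation_scalar: float = -0.74   # valence multiplier when negated
    booster_incr: float = 0.293      # magnitude of a booster shift
    booster_damp: tuple = (1.0, 0.95, 0.9)  # damping at distance 1..3
    caps_incr: float = 0.733         # ALL-CAPS emphasis added toward the sign
    alpha: float = 15.0              # normalization constant
    excl_incr: float = 0.292         # per-"!" emphasis
    max_excl: int = 3                # at most three "!" count
    but_before: float = 0.5          # clause weights around "but"
    but_after: float = 1.5


DEFAULT_NEGATIONS = frozenset(
    """not no never neither nobody none nothing nowhere cannot without
    isnt isn't arent aren't wasnt wasn't werent weren't dont don't doesnt
    doesn't didnt didn't cant can't couldnt couldn't wont won't wouldnt
    wouldn't shouldnt shouldn't aint ain't""".split()
)

DEFAULT_BOOSTERS = {
    "very": +1, "really": +1, "extremely": +1, "absolutely": +1, "so": +1,
    "totally": +1, "incredibly": +1, "super": +1, "completely": +1,
    "slightly": -1, "somewhat": -1, "barely": -1, "kinda": -1, "marginally": -1,
    "a bit": -1,  # matched as the token "bit" never appears; kept for config clarity
}


@dataclass
class SentimentLexicon:
    """Word and emoji valences plus rule word lists.

    Word lookups are case-insensitive; emoji lookups are exact.
    """

    words: dict[str, float]
    emoji: dict[str, float] = field(default_factory=dict)
    boosters: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BOOSTERS))
    negations: frozenset = DEFAULT_NEGATIONS
    rules: RuleConfig = field(default_factory=RuleConfig)

    def __post_init__(self):
        self.words = {w.lower(): float(v) for w, v in self.words.items()}
        self._emoji_re: Optional[re.Pattern] = None

    def emoji_pattern(self) -> Optional[re.Pattern]:
        if self.emoji and self._emoji_re is None:
            alts = sorted(self.emoji, key=len, reverse=True)
            self._emoji_re = re.compile("|".join(re.escape(e) for e in alts))
        return self._emoji_re


def load_lexicon(path=None, rules: Optional[RuleConfig] = None) -> SentimentLexicon:
    """Load a term,valence CSV; defaults to the packaged mini-lexicon."""
    if path is None:
        path = data_path("mini_lexicon.csv")
    words: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header and _is_float(header[-1]):  # headerless file
            fh.seek(0)
            reader = csv.reader(fh)
        for row in reader:
            if len(row) >= 2 and _is_float(row[1]):
                words[row[0]] = float(row[1])
    return SentimentLexicon(words=words, rules=rules or RuleConfig())


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def augment_emoji(lex: SentimentLexicon, emoji_file) -> SentimentLexicon:
    """Return a new lexicon with emoji,valence CSV rows merged in.

    Malformed rows are skipped with a warning; duplicate emoji keep the last
    value seen (warned).
    """
    merged = dict(lex.emoji)
    with open(emoji_file, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip().lower() == "emoji"):
                continue
            if len(row) < 2 or not _is_float(row[1]):
                logger.warning("skipping malformed emoji row %d: %r", lineno, row)
                continue
            key = row[0]
            if key in merged:
                logger.warning("duplicate emoji %r: last value wins", key)
            merged[key] = float(row[1])
    return SentimentLexicon(
        words=dict(lex.words), emoji=merged, boosters=dict(lex.boosters),
        negations=lex.negations, rules=lex.rules,
    )


# ---------------------------------------------------------------------------
# Scoring

_SENTENCE_RE = re.compile(r"[^.!?\n]+[.!?]*")
_STRIP_CHARS = string.punctuation + "“”‘’"


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation (. ! ? newline); no empty sentences."""
    out = []
    for chunk in _SENTENCE_RE.findall(text or ""):
        chunk = chunk.strip()
        if chunk and chunk.strip(_STRIP_CHARS + " "):
            out.append(chunk)
    return out


def _tokenize(sentence: str, lex: SentimentLexicon) -> list[str]:
    """Whitespace tokens with punctuation stripped; known emoji separated out."""
    pat = lex.emoji_pattern()
    tokens: list[str] = []
    for chunk in sentence.split():
        if pat:
            pieces = []
            last = 0
            for m in pat.finditer(chunk):
                pieces.append(chunk[last:m.start()])
                pieces.append(m.group())
                last = m.end()
            pieces.append(chunk[last:])
        else:
            pieces = [chunk]
        for piece in pieces:
            if piece in lex.emoji:
                tokens.append(piece)
                continue
            piece = piece.strip(_STRIP_CHARS)
            if piece:
                tokens.append(piece)
    return tokens


def _token_valence(i: int, tokens: list[str], lex: SentimentLexicon, cap_diff: bool) -> float:
    tok = tokens[i]
    if tok in lex.emoji:
        return lex.emoji[tok]
    low = tok.lower()
    if low in lex.boosters or low in lex.negations or low not in lex.words:
        return 0.0
    v = lex.words[low]
    cfg = lex.rules
    if cap_diff and tok.isupper() and len(tok) > 1:
        v += cfg.caps_incr if v > 0 else -cfg.caps_incr
    # booster and negation context: up to three preceding tokens
    negated = False
    for dist in (1, 2, 3):
        j = i - dist
        if j < 0:
            break
        prior = tokens[j].lower()
        if prior in lex.boosters:
            shift = cfg.booster_incr * lex.boosters[prior] * cfg.booster_damp[dist - 1]
            v += shift if v > 0 else -shift
        if prior in lex.negations:
            negated = True
    if negated:
        v *= cfg.negation_scalar
    return v


def sentence_compound(sentence: str, lex: SentimentLexicon) -> float:
    """Compound score of one sentence, in [-1, 1]."""
    cfg = lex.rules
    tokens = _tokenize(sentence, lex)
    if not tokens:
        return 0.0
    uppers = [t for t in tokens if t.isupper() and len(t) > 1 and t.isalpha()]
    cap_diff = 0 < len(uppers) < sum(t.isalpha() for t in tokens)
    valences = [_token_valence(i, tokens, lex, cap_diff) for i in range(len(tokens))]
    lowered = [t.lower() for t in tokens]
    if "but" in lowered:
        bi = lowered.index("but")
        valences = [
            v * (cfg.but_before if i < bi else cfg.but_after if i > bi else 1.0)
            for i, v in enumerate(valences)
        ]
    total = sum(valences)
    if total != 0.0:
        ep = min(sentence.count("!"), cfg.max_excl) * cfg.excl_incr
        total += ep if total > 0 else -ep
    return normalize(total, cfg.alpha)


def normalize(x: float, alpha: float = 15.0) -> float:
    """Squash an unbounded valence sum into [-1, 1]."""
    score = x / sqrt(x * x + alpha)
    return max(-1.0, min(1.0, score))


@dataclass(frozen=True)
class TweetSentiment:
    sentence_compounds: tuple[float, ...]
    score: float
    polarity: str


def classify_polarity(score: float) -> str:
    if score >= POLARITY_THRESHOLD:
        return POSITIVE
    if score <= -POLARITY_THRESHOLD:
        return NEGATIVE
    return NEUTRAL


def score_tweet(text: str, lex: SentimentLexicon) -> TweetSentiment:
    """Score a post: mean of nonzero sentence compounds, then polarity."""
    compounds = tuple(sentence_compound(s, lex) for s in split_sentences(text))
    nonzero = [c for c in compounds if c != 0.0]
    score = sum(nonzero) / len(nonzero) if nonzero else 0.0
    return TweetSentiment(sentence_compounds=compounds, score=score,
                          polarity=classify_polarity(score))
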