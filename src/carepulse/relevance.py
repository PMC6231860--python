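"""Supervised relevance classification of patient-experience posts.

Keyword retrieval is deliberately broad; a linear max-margin classifier
separates genuine patient-experience posts (an exposure to health care — the
poster's own, a friend's or a relative's) from the rest.  Features are
TF-IDF-weighted unigrams and bigrams over Twitter-aware tokens (hashtags and
emoticons survive as single tokens, @-mentions and stop words are dropped),
plus two binary flags: does the post mention hospital staff, and does it
reference the poster or a family member.  The flags are computed on the raw
token stream *before* stop-word removal so that "my"/"me" stay visible.

Evaluation is 10-fold cross-validation with the vocabulary, IDF weights and
top-k feature selection fitted inside each training fold (no leakage), and
an overfit check comparing train-fold vs test-fold performance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.feature_selection import chi2 as chi2_score
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from ._data import data_path, read_word_list
from .ingest import TweetRecord, URL_RE

RELEVANT = "RELEVANT"
IRRELEVANT = "IRRELEVANT"

# ---------------------------------------------------------------------------
# Tokenization

_EMOTICON = r"[<>]?[:;=8][\-o\*']?[\)\]\(\[dDpP/\:\}\{@\|\\]|<3|</3"
_TOKEN_RE = re.compile(
    rf"{URL_RE.pattern}|{_EMOTICON}|[@#]\w+|\w+(?:['’]\w+)*|[^\w\s]",
    re.IGNORECASE,
)

_STOPWORDS: Optional[frozenset] = None


def default_stopwords() -> frozenset:
    global _STOPWORDS
    if _STOPWORDS is None:
        _STOPWORDS = frozenset(read_word_list(data_path("stopwords.txt")))
    return _STOPWORDS


def raw_tokenize(text: str) -> list[str]:
    """Twitter-aware tokens, lowercased, nothing removed."""
    return [t.lower() for t in _TOKEN_RE.findall(text or "")]


def tokenize(text: str, stopwords: Optional[frozenset] = None) -> list[str]:
    """Tokens with @-mentions and stop words removed."""
    if stopwords is None:
        stopwords = default_stopwords()
    return [
        t for t in raw_tokenize(text)
        if not t.startswith("@") and t not in stopwords
    ]


def _ngrams(tokens: Sequence[str], ngram_range: tuple[int, int] = (1, 2)) -> list[str]:
    lo, hi = ngram_range
    out = []
    for n in range(lo, hi + 1):
        out.extend(" ".join(tokens[i:i + n]) for i in range(len(tokens) - n + 1))
    return out


# ---------------------------------------------------------------------------
# Features


@dataclass(frozen=True)
class LabeledExample:
    tweet: TweetRecord
    label: str

    def __post_init__(self):
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"label must be {RELEVANT} or {IRRELEVANT}")


class FeatureSpec:
    """TF-IDF n-gram block plus two appended binary reference features."""

    def __init__(
        self,
        ngram_range: tuple[int, int] = (1, 2),
        vocabulary: Optional[dict] = None,
        staff_lexicon: Optional[Sequence[str]] = None,
        self_family_lexicon: Optional[Sequence[str]] = None,
    ):
        self.ngram_range = tuple(ngram_range)
        self.staff_lexicon = frozenset(
            staff_lexicon if staff_lexicon is not None
            else read_word_list(data_path("staff_lexicon.txt"))
        )
        self.self_family_lexicon = frozenset(
            self_family_lexicon if self_family_lexicon is not None
            else read_word_list(data_path("self_family_lexicon.txt"))
        )
        self._vectorizer = TfidfVectorizer(
            analyzer=self._analyze, vocabulary=vocabulary, lowercase=False
        )
        self.fitted = vocabulary is not None

    def _analyze(self, text: str) -> list[str]:
        return _ngrams(tokenize(text), self.ngram_range)

    @property
    def vocabulary(self) -> dict:
        return self._vectorizer.vocabulary_

    @property
    def n_features(self) -> int:
        return len(self._vectorizer.vocabulary_) + 2

    def fit(self, texts: Sequence[str]) -> "FeatureSpec":
        self._vectorizer.fit(texts)
        self.fitted = True
        return self

    def _extras(self, texts: Sequence[str]) -> np.ndarray:
        rows = np.zeros((len(texts), 2))
        for i, text in enumerate(texts):
            raw = set(raw_tokenize(text))  # before stop-word removal
            rows[i, 0] = float(bool(raw & self.staff_lexicon))
            rows[i, 1] = float(bool(raw & self.self_family_lexicon))
        return rows

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        """Sparse [tfidf n-grams | staff flag | self/family flag] matrix."""
        if not self.fitted:
            raise RuntimeError("FeatureSpec must be fitted before transform")
        X = self._vectorizer.transform(texts)
        return sp.hstack([X, sp.csr_matrix(self._extras(texts))], format="csr")

    def restricted(self, terms: Sequence[str]) -> "FeatureSpec":
        """A new, unfitted spec limited to the given n-gram vocabulary."""
        return FeatureSpec(
            ngram_range=self.ngram_range,
            vocabulary={t: i for i, t in enumerate(terms)},
            staff_lexicon=self.staff_lexicon,
            self_family_lexicon=self.self_family_lexicon,
        )


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    max_features: int = 15_000
    selection: str = "weight"   # "weight" (|coef| rank) or "chi2"
    C: float = 1.0
    n_folds: int = 10
    seed: int = 0
    ngram_range: tuple[int, int] = (1, 2)


@dataclass
class TrainedRelevanceModel:
    spec: FeatureSpec
    coef: np.ndarray
    intercept: float
    config: TrainConfig

    def decision_function(self, texts: Sequence[str]) -> np.ndarray:
        X = self.spec.transform(texts)
        return np.asarray(X @ self.coef) + self.intercept

    def save(self, path) -> None:
        vocab = [None] * len(self.spec.vocabulary)
        for term, idx in self.spec.vocabulary.items():
            vocab[idx] = term
        idf = getattr(self.spec._vectorizer, "idf_", None)
        obj = {
            "schema_version": 1,
            "ngram_range": list(self.spec.ngram_range),
            "vocabulary": vocab,
            "idf": None if idf is None else list(map(float, idf)),
            "coef": list(map(float, self.coef)),
            "intercept": float(self.intercept),
            "staff_lexicon": sorted(self.spec.staff_lexicon),
            "self_family_lexicon": sorted(self.spec.self_family_lexicon),
            "config": {**self.config.__dict__, "ngram_range": list(self.config.ngram_range)},
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "TrainedRelevanceModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        if obj.get("schema_version") != 1:
            raise ValueError("unsupported model schema")
        cfg = TrainConfig(**{**obj["config"], "ngram_range": tuple(obj["config"]["ngram_range"])})
        spec = FeatureSpec(
            ngram_range=tuple(obj["ngram_range"]),
            vocabulary={t: i for i, t in enumerate(obj["vocabulary"])},
            staff_lexicon=obj["staff_lexicon"],
            self_family_lexicon=obj["self_family_lexicon"],
        )
        if obj["idf"] is not None:
            spec._vectorizer.idf_ = np.asarray(obj["idf"], dtype=float)
        return cls(spec=spec, coef=np.asarray(obj["coef"], dtype=float),
                   intercept=obj["intercept"], config=cfg)


@dataclass
class CVReport:
    folds: list[dict] = field(default_factory=list)

    def _mean(self, key: str) -> float:
        return float(np.mean([f[key] for f in self.folds]))

    @property
    def mean_f1(self) -> float:
        return self._mean("f1")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def overfit_gap(self) -> float:
        """Mean train-fold F1 minus mean test-fold F1."""
        return self._mean("train_f1") - self._mean("f1")


def _fit_classifier(X, y, config: TrainConfig) -> LinearSVC:
    clf = LinearSVC(C=config.C, loss="hinge", max_iter=20_000, random_state=config.seed)
    clf.fit(X, y)
    return clf


def _select_terms(spec: FeatureSpec, X, y, config: TrainConfig) -> list[str]:
    """Top-k n-gram terms; extras are always kept and never ranked."""
    terms = [None] * len(spec.vocabulary)
    for term, idx in spec.vocabulary.items():
        terms[idx] = term
    n_ngram = len(terms)
    if n_ngram <= config.max_features:
        return terms
    if config.selection == "chi2":
        scores, _ = chi2_score(X[:, :n_ngram], y)
        scores = np.nan_to_num(scores)
    elif config.selection == "weight":
        clf = _fit_classifier(X, y, config)
        scores = np.abs(clf.coef_.ravel()[:n_ngram])
    else:
        raise ValueError(f"unknown selection {config.selection!r}")
    order = sorted(range(n_ngram), key=lambda i: (-scores[i], terms[i]))
    return [terms[i] for i in order[: config.max_features]]


def _fit_pipeline(texts, y, config: TrainConfig) -> tuple[FeatureSpec, LinearSVC]:
    spec = FeatureSpec(ngram_range=config.ngram_range).fit(texts)
    X = spec.transform(texts)
    kept = _select_terms(spec, X, y, config)
    if len(kept) < len(spec.vocabulary):
        spec = spec.restricted(kept).fit(texts)
        X = spec.transform(texts)
    return spec, _fit_classifier(X, y, config)


def _metrics(y_true, y_pred, prefix: str = "") -> dict:
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, pos_label=RELEVANT, average="binary", zero_division=0
    )
    acc = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return {f"{prefix}precision": float(p), f"{prefix}recall": float(r),
            f"{prefix}f1": float(f1), f"{prefix}accuracy": acc}


def train(
    examples: Sequence[LabeledExample], config: Optional[TrainConfig] = None
) -> tuple[TrainedRelevanceModel, CVReport]:
    """Fit the relevance model and report 10-fold cross-validation metrics.

    The vocabulary, IDF weights and feature selection are re-fitted inside
    each training fold; the returned model is fitted on all examples.
    Deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    texts = [ex.tweet.text for ex in examples]
    y = np.array([ex.label for ex in examples])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need >= {config.n_folds} examples per class for {config.n_folds}-fold CV"
        )
    report = CVReport()
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in skf.split(texts, y):
        tr_texts = [texts[i] for i in train_idx]
        te_texts = [texts[i] for i in test_idx]
        spec, clf = _fit_pipeline(tr_texts, y[train_idx], config)
        fold = _metrics(y[test_idx], clf.predict(spec.transform(te_texts)))
        fold.update(_metrics(y[train_idx], clf.predict(spec.transform(tr_texts)), "train_"))
        report.folds.append(fold)
    spec, clf = _fit_pipeline(texts, y, config)
    model = TrainedRelevanceModel(
        spec=spec, coef=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]),
        config=config,
    )
    return model, report


def predict(
    model: TrainedRelevanceModel, tweets: Sequence[TweetRecord]
) -> tuple[list[str], np.ndarray]:
    """Labels and margin scores; RELEVANT iff the margin is > 0."""
    margins = model.decision_function([t.text for t in tweets])
    labels = [RELEVANT if m > 0 else IRRELEVANT for m in margins]
    return labels, margins
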