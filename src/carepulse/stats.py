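"""Reporting statistics: rates, quantile stratification, rank tests.

The surveillance read-outs are

* printed percentages (half-away-from-zero rounding at 2 decimals),
* the *average sentiment polarity rate* — (positive - negative) post counts
  per 100,000 state residents, averaged (unweighted by default) over member
  states for a region,
* the *patient experience tweet rate* — posts per 100,000 residents,
* a metro-vs-nonmetro comparison harness: pooled nonzero sentiment scores are
  split at empirical quartiles into Q1 (most negative) .. Q4 (most positive),
  and each stratum is compared with a two-sided Mann-Whitney U test plus
  Cohen's d (pooled-SD standardized mean difference), at alpha = 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geoloc import census_region_map

NATIONAL = "NATIONAL"
QUANTILES = ("ALL", "Q1", "Q2", "Q3", "Q4")

#: states excluded from the metro comparison (fully-urban DC, no-region PR).
METRO_ANALYSIS_EXCLUDED_STATES = ("DC", "PR")


def percentage(numerator: int, denominator: int) -> float:
    """100*n/d rounded half-away-from-zero to 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    frac = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    sign = -1 if frac < 0 else 1
    return float(sign * abs(frac).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def polarity_rate(n_pos: int, n_neg: int, population: float) -> float:
    """Signed (positive - negative) posts per 100,000 residents."""
    if population <= 0:
        raise ValueError("population must be positive")
    return (n_pos - n_neg) / population * 100_000


def tweet_rate(n_tweets: int, population: float) -> float:
    """Posts per 100,000 residents."""
    if population <= 0:
        raise ValueError("population must be positive")
    return n_tweets / population * 100_000


def region_polarity_rate(
    state_rates: Sequence[float], populations: Optional[Sequence[float]] = None
) -> float:
    """Mean member-state polarity rate; population-weighted when given."""
    if len(state_rates) == 0:
        raise ValueError("region has no member states with data")
    if populations is None:
        return float(np.mean(state_rates))
    w = np.asarray(populations, dtype=float)
    return float(np.average(np.asarray(state_rates, dtype=float), weights=w))


@dataclass(frozen=True)
class StateYearCounts:
    state: str
    year: int
    n_pos: int
    n_neg: int
    n_neutral: int
    population: float

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_neutral) < 0:
            raise ValueError("counts must be nonnegative")
        if self.population <= 0:
            raise ValueError("population must be positive")


# ---------------------------------------------------------------------------
# Quantile stratification


def quantile_partition(scores: Sequence[float]) -> list[np.ndarray]:
    """Split scores into Q1..Q4 by empirical quartiles of the pooled data.

    Boundaries are the 25/50/75th percentiles (linear interpolation); a score
    exactly on a boundary goes to the lower bin.  Returns four index arrays
    into ``scores``.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 scores to form quartiles")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    bins = [
        np.nonzero(x <= q1)[0],
        np.nonzero((x > q1) & (x <= q2))[0],
        np.nonzero((x > q2) & (x <= q3))[0],
        np.nonzero(x > q3)[0],
    ]
    return bins


# ---------------------------------------------------------------------------
# Rank test and effect size


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of ``a``, p).

    U is computed from rank sums with midranks for ties.  The p value uses
    exact enumeration when both samples are at most ``exact_limit`` and tie
    free, otherwise the tie-corrected, continuity-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and max(a.size, b.size) <= exact_limit
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation: d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# Comparison harness


@dataclass(frozen=True)
class QuantileTestResult:
    scope: str          # NATIONAL or a census region
    quantile: str       # ALL, Q1..Q4
    n_metro: int
    n_nonmetro: int
    mean_metro: float
    sd_metro: float
    mean_nonmetro: float
    sd_nonmetro: float
    u_statistic: Optional[float]
    p_value: Optional[float]
    cohens_d: Optional[float]       # always computed when defined
    d_reported: Optional[float]     # shown only when p < alpha (table policy)
    testable: bool


def _group_stats(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def _compare_one(scope: str, quantile: str, metro: np.ndarray, nonmetro: np.ndarray,
                 alpha: float) -> QuantileTestResult:
    mean_m, sd_m = _group_stats(metro)
    mean_n, sd_n = _group_stats(nonmetro)
    testable = metro.size > 0 and nonmetro.size > 0
    u = p = d = d_rep = None
    if testable:
        u, p = mann_whitney(metro, nonmetro)
        if metro.size >= 2 and nonmetro.size >= 2:
            try:
                d = cohens_d(metro, nonmetro)
            except ValueError:
                d = None
        if d is not None and p < alpha:
            d_rep = d
    return QuantileTestResult(
        scope=scope, quantile=quantile,
        n_metro=int(metro.size), n_nonmetro=int(nonmetro.size),
        mean_metro=mean_m, sd_metro=sd_m, mean_nonmetro=mean_n, sd_nonmetro=sd_n,
        u_statistic=u, p_value=p, cohens_d=d, d_reported=d_rep, testable=testable,
    )


def compare_table(
    data: pd.DataFrame,
    alpha: float = 0.001,
    exclude_states: Sequence[str] = METRO_ANALYSIS_EXCLUDED_STATES,
) -> pd.DataFrame:
    """Metro-vs-nonmetro comparison at national and regional level.

    ``data`` needs columns ``score`` (per-post sentiment), ``state`` (two-
    letter code) and ``metro`` (boolean).  DC and PR are excluded, as are
    zero scores (posts whose text carried no lexicon term at all).  For each
    scope (national + 4 regions) the pooled nonzero scores are stratified at
    the scope's own empirical quartiles, and each of ALL, Q1..Q4 is tested.
    Returns the 25-row tidy table.
    """
    df = data[~data["state"].isin(list(exclude_states))].copy()
    df = df[df["score"] != 0.0]
    regions = census_region_map()
    df["region"] = df["state"].map(regions)
    rows: list[QuantileTestResult] = []
    scopes = [(NATIONAL, df)] + [
        (reg, df[df["region"] == reg])
        for reg in ("NORTHEAST", "MIDWEST", "SOUTH", "WEST")
    ]
    for scope, sub in scopes:
        scores = sub["score"].to_numpy(dtype=float)
        is_metro = sub["metro"].to_numpy(dtype=bool)
        rows.append(_compare_one(scope, "ALL", scores[is_metro], scores[~is_metro], alpha))
        if scores.size >= 4:
            bins = quantile_partition(scores)
        else:
            bins = [np.array([], dtype=int)] * 4
        for name, idx in zip(QUANTILES[1:], bins):
            m = scores[idx][is_metro[idx]]
            n = scores[idx][~is_metro[idx]]
            rows.append(_compare_one(scope, name, m, n, alpha))
    return pd.DataFrame([r.__dict__ for r in rows])
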