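# Methods

This note documents the models, conventions and design choices behind
`carepulse`, module by module, including what the synthetic-data generator
does and does not emulate.

## Corpus definition and structural filters

A post enters the candidate corpus iff at least one keyword rule fires. A
ruleset is a set of keyword *classes* (medical facilities and staff, medical
procedures, hospital visits and stays, medications, hospital bills and
insurance, care condition, pain) plus *rules*, each a conjunction of class
names; the ruleset fires when any rule has every class matched. Keywords are
matched case-insensitively on word boundaries; a per-class prefix mode
("recover" also hitting "recovery") exists but is off by default, since
exact-word semantics are the more conservative reading. Only the
care-condition list in the shipped default ruleset is a curated list; the
other six classes are small, clearly labeled placeholders meant to be
replaced in any real deployment (the config is an editable YAML file).

Structural filtering removes reposts, URL-bearing posts and duplicate ids
(first occurrence wins, stream order). URL detection is a scheme-based regex
(`http://`, `https://`) plus bare `www.` prefixes, so `t.co` short links
count. Removal reasons are counted with precedence repost > URL > duplicate,
which makes the report conserve counts exactly:
`n_input = n_kept + Σ removals`. The filter is idempotent.

## Relevance classifier

Tokenization is Twitter-aware (regex-based): URLs, `#hashtags`, `@mentions`
and common emoticons survive as single tokens; everything is lowercased;
`@mentions` and stop words (an editable shipped list) are then removed.
Features are TF-IDF-weighted unigrams and bigrams, plus two binary flags
appended after the n-gram block: a hospital-staff reference and a
self/family reference, both computed on the raw token stream *before*
stop-word removal so that "my"/"me" remain visible. The flags are raw
binary, not TF-IDF-scaled. Both word lists are editable data files.

The classifier is a linear max-margin fit (hinge loss, C = 1.0,
configurable). When the fitted vocabulary exceeds `max_features` (default
15,000), terms are ranked by absolute coefficient from a preliminary
full-vocabulary fit (χ² ranking available behind a flag), with lexicographic
tie-breaking for determinism. Evaluation is stratified 10-fold
cross-validation; the vocabulary, IDF weights and feature selection are
re-fitted inside each training fold, so test-fold terms outside the fold's
vocabulary are simply ignored (no leakage). The report carries per-fold
precision/recall/F1/accuracy for the relevant class and the
train-minus-test F1 gap as an overfitting measure. Models serialize to a
single versioned JSON file (vocabulary, IDF, weights, config).

## Geolocation

Signals are used with GPS precedence: coordinates, when present, are
resolved by point-in-polygon against state boundary polygons (shapely,
`covers` semantics so boundary points count as inside; ties between
adjacent polygons go to the earlier feature in file order). Otherwise the
profile string is normalized (lowercase, trim, whitespace collapse,
emoji/symbol stripping, comma/pipe/slash segmentation), screened against a
junk-location library (exact entries plus regex patterns), and geocoded
against an offline gazetteer; the whole string is tried first, then its
first segment. The gazetteer returns an ordered candidate list — ranked
population-descending in the shipped fixtures, since "take the first
candidate" requires a defined order — and the first candidate decides the
outcome. The geocoder is an interface; a live backend can be plugged in
with the same contract.

Outcome statuses partition every post: `US_STATE` (50 states + DC + PR +
VI), `NON_US`, `INSUFFICIENT` (string present but junk or unresolvable),
`NONE` (no location field, or empty before normalization). The
INSUFFICIENT/NONE distinction is: NONE means nothing was provided,
INSUFFICIENT means something was provided but unusable. States among the 50
+ DC carry one of the four census regions; PR and VI carry none.

## Sentiment scoring

Sentences are split on terminal punctuation (`.` `!` `?` and newline). Each
sentence's compound is the sum of its tokens' signed valences, adjusted by
rules, then normalized by `x → x/√(x² + α)` with α = 15, which bounds every
compound in [−1, 1] for arbitrary input. Implemented rules (all constants
in one `RuleConfig` block):

- negation within a 3-token look-back window scales the valence by −0.74;
- booster words shift the magnitude by 0.293 toward the valence's sign,
  damped with distance (×1.0, ×0.95, ×0.9);
- an ALL-CAPS word (when the sentence is not all caps) gains 0.733 toward
  its sign;
- up to three `!` add 0.292 each toward the sign of the sentence sum;
- tokens before "but" are weighted ×0.5, tokens after ×1.5.

Idiom and special-case tables of the full lexicon method are deliberately
out of scope. Every rule is odd under valence negation, so mirroring the
lexicon (w → −v) negates every score exactly — a property the tests
exploit. Word lookups are case-insensitive; emoji lookups are exact, and an
emoji participates in the sum exactly like a word. Emoji augmentation merges
an `emoji,valence` CSV into the lexicon (malformed rows skipped with a
warning, duplicate emoji last-wins with a warning).

The per-post score is the mean of the *nonzero* sentence compounds — a
sentence with no lexicon term is treated as uninformative rather than as
neutral evidence — and 0 when all compounds are zero. Polarity thresholds
are inclusive: POSITIVE at score ≥ 0.3, NEGATIVE at ≤ −0.3, NEUTRAL
between. Two "exclude neutral" conventions coexist downstream and are kept
explicit: the comparison harness excludes only exact-zero scores (so
mildly-negative/positive strata remain populated), while polarity-based
fraction and temporal analyses exclude the whole neutral band. The shipped
mini-lexicon (42 words, 12 emoji) is for tests and fixtures; a full
`term,valence` lexicon file loads through the same reader.

## Metro classification

METRO iff the point lies inside at least one urbanized-area polygon
(population ≥ 50,000); points inside only urban clusters (5,000–49,999) or
outside every urban polygon are NONMETRO. Boundary points count as inside.
Adding cluster polygons can therefore never demote a METRO point. The
DC/PR exclusion for the population-size comparison is applied in the stats
module, not here.

## Temporal profiles

Timestamps arrive in UTC and are converted with the IANA zone database
(DST-aware) using one dominant (most-populous) timezone per state, stored
in an editable CSV covering the 50 states + DC — a deliberate
simplification for multi-zone states like TX and FL. Profiles bin
POSITIVE/NEGATIVE posts by local clock hour [h, h+1) or ISO weekday (Monday
first) and report the per-bin negative fraction neg/(pos+neg), which is NaN
(undefined, not zero) for empty bins. Fractions are among polar posts only;
neutral posts are excluded upstream.

## Statistics

- `percentage` rounds 100·n/d half-away-from-zero to 2 decimals (Decimal
  arithmetic, so 69.425 prints as 69.43, never banker's rounding).
- *Average sentiment polarity rate* = (n_pos − n_neg)/population × 100,000,
  signed; a region's value is the unweighted mean over member states, with
  a population-weighted mode behind a flag.
- *Tweet rate* = n/population × 100,000.
- Quartile stratification: boundaries are the empirical 25/50/75th
  percentiles (linear interpolation) of the pooled nonzero scores *within
  the scope* (national boundaries for national rows, regional for regional
  rows); a score exactly on a boundary goes to the lower bin. Bin means are
  non-decreasing Q1 → Q4 by construction.
- Mann-Whitney U: U from rank sums with midranks; two-sided p by exact
  enumeration when both groups are at most `exact_limit` (default 8) and
  tie-free, otherwise the tie-corrected, continuity-corrected normal
  approximation (scipy backend). The approximation agrees with exhaustive
  enumeration within 0.02 for tie-free groups of 5–8; below that the exact
  branch is authoritative — at 3v3 no normal approximation is that close.
- Cohen's d = (mean_a − mean_b)/pooled SD with (n−1) weighting; undefined
  (error) at zero pooled SD. In the comparison table d is always computed
  when defined, but *reported* only for rows significant at α = 0.001,
  matching the reporting policy of the table it mirrors.
- The comparison harness drops DC and PR and exact-zero scores, then emits
  25 tidy rows: (national + 4 regions) × (ALL, Q1–Q4), each with group
  sizes, means, SDs, U, p, d. A scope-stratum with an empty group is marked
  not-testable rather than fabricating a p-value.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; its
defaults *are* the study conditions the pipeline is designed around and are
set once, not tuned: marginal relevance rate 0.101, marginal URL rate
0.6612 with an 18× irrelevance odds multiplier, repost rate 0.40, GPS /
missing / junk / non-US profile rates 0.03 / 0.35 / 0.145 / 0.19, metro
fraction 0.69, and a two-Gaussian sentiment mixture N(−0.50, 0.219) /
N(+0.42, 0.219) with negative weight 0.522, which solves exactly to a
pooled mean of −0.06 and SD of 0.509 (a symmetric bimodal shape). Given the
marginal URL rate and the odds multiplier, the per-class URL probabilities
are solved by root-finding so the empirical odds ratio of irrelevance given
a URL concentrates near the configured multiplier.

Post text is a keyword-class template sentence (chosen so it contains no
sentiment-lexicon, booster, negation or "but" token — its compound is
exactly 0) followed by a sentence of plain lexicon words. The word set is
chosen from a precomputed table of all 1–3-word valence sums of the
mini-lexicon by nearest-sum lookup against the target's inverse
normalization x = c·√(α/(1−c²)), which lands the scorer within ±0.05 of the
target compound without inverting the rule machinery analytically. Targets
are clipped to ±0.92 to stay within the lexicon's reachable range.

Geography: 8 rectangular toy states (two per census region, at fictitious
but valid coordinates), each containing one urbanized rectangle and one
urban-cluster rectangle; GPS points are sampled consistently with the
post's true metro flag (rejection sampling for rural points); profile
strings come from a gazetteer whose city points sit inside the urbanized
rectangles and whose "falls" points sit in open country, so profile-
geocoded posts also classify correctly. Fixture generation self-checks
these invariants (every US gazetteer point round-trips to its state; metro
city points classify METRO).

Timestamps: a local hour is drawn from a day-heavy activity curve, attached
to the true state's timezone, and converted to UTC. Night hours (8 pm–10
am) multiply the odds of drawing the negative mixture component by
`night_negative_boost` (default 1.35); the day weight is solved by
root-finding so the activity-weighted marginal mixture weight is preserved
— the boost reshapes *when* negativity appears without shifting the overall
mixture mean. Truth labels (relevance, target score, state, metro flag,
location mode, local hour) go to a sidecar only; a schema test asserts the
main stream carries none of them.

What the generator does **not** emulate: real linguistic diversity (texts
are templated), user-level structure and repost dynamics, seasonal or
yearly drift, multi-zone states, and gazetteer ambiguity beyond one planted
ambiguous place name. Passing recovery tests therefore demonstrates that
the pipeline measures what the generator plants at realistic marginals —
not that the classifier or geocoder would reach any particular accuracy on
real, messy streams.

## Validation sizes and numerical choices

The test suite and acceptance script use problem sizes chosen to make
sampling noise small relative to the tolerances they check: 20,000-post
corpora (20 seeds in the recovery suite, 5 in the acceptance script),
10,000 random points for the geometry oracle (an independent ray-casting
implementation, not shapely), 10,000 random token sequences for sentiment
bounds/symmetry, 1,000 null replicates for the type-I rate at α = 0.001,
and 100 replicates at n = 2,000/group for power under a −0.2 shift. All
randomness flows from explicit seeds; the generator is byte-identical for a
fixed config.

Known limitations: the placeholder keyword lists bound what ingest can
retrieve; the mini-lexicon is far smaller than a production sentiment
lexicon; first-candidate geocoding inherits the gazetteer's ranking; one
timezone per state mislabels local hours for a minority of real posters;
and the quartile boundaries are scope-local, so strata are not comparable
across scopes by absolute score range.
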