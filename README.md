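# carepulse

Surveillance of patient-experience sentiment on social media.

People describe the health care they receive — hospital stays, clinic
visits, medications, bills, pain — in public short-form posts. `carepulse`
turns such a stream into geographically and temporally stratified sentiment
read-outs: which US states and census regions skew negative about their
care, whether metropolitan and nonmetropolitan posters differ, and how the
negative fraction moves across the local hour of day and day of week.

The package is aimed at digital-epidemiology / infodemiology researchers who
need the whole chain — filtering, relevance classification, geolocation,
sentiment scoring, urban/rural stratification and the comparison statistics
— as tested, reusable components rather than a one-off analysis script.

## Pipeline

1. **ingest** — parse a JSON Lines stream of posts; keep a post iff a
   keyword rule fires (classes such as *care condition*: monitor, heal,
   recover, care, cure, dying, dead, sicker, sick, ill, illness, condition);
   drop reposts, URL-bearing posts (overwhelmingly promotional rather than
   first-person experience) and duplicate ids.
2. **relevance** — a linear max-margin (SVM) classifier over TF-IDF
   unigrams/bigrams of Twitter-aware tokens plus two binary flags (mentions
   hospital staff; references self or family), evaluated by 10-fold
   cross-validation with per-fold vocabulary fitting and an overfit check.
3. **geoloc** — infer a US state (or NON_US / INSUFFICIENT / NONE) from GPS
   coordinates when present, else from the free-text profile location via
   normalization, a junk-location library ("in your heart", "with aliens",
   …) and an offline gazetteer whose *first* candidate is taken; states map
   to the four census regions.
4. **sentiment** — lexicon-and-rule compound scoring per sentence,

   ```
   compound = x / sqrt(x² + 15),   x = Σ rule-adjusted valences
   ```

   with negation (×−0.74 within a 3-token window), boosters (±0.293),
   ALL-CAPS and "!" emphasis, "but" re-weighting, and an emoji valence
   lexicon. Per-post score = mean of nonzero sentence compounds; polarity is
   POSITIVE if score ≥ 0.3, NEGATIVE if ≤ −0.3, else NEUTRAL.
5. **metro** — METRO iff the point lies inside an *urbanized area* polygon
   (population ≥ 50,000); urban clusters (5,000–49,999) and open country are
   NONMETRO.
6. **temporal** — DST-aware conversion to the state's dominant timezone;
   hour-of-day and day-of-week profiles of the negative fraction
   neg/(pos+neg) among polar posts.
7. **stats** — printed-percentage arithmetic (half-away-from-zero at 2
   decimals); *average sentiment polarity rate* = (n_pos − n_neg) per
   100,000 residents (region = unweighted mean over member states); *tweet
   rate* = posts per 100,000 residents; and the metro-vs-nonmetro comparison
   harness: pooled nonzero scores split at empirical quartiles into Q1 (most
   negative) … Q4 (most positive), each stratum tested with a two-sided
   Mann-Whitney U (exact below a small-n limit, tie-corrected normal
   approximation otherwise) and Cohen's d, reported at α = 0.001, with DC
   and PR excluded.
8. **synth** — a deterministic generator of labeled synthetic corpora and
   mutually-consistent geographic fixtures, so every stage is testable
   offline; see `docs/methods.md`.

## Worked example

```python
import tempfile
from carepulse import geoloc as G, metro as M, sentiment as S, stats, synth
from carepulse.pipeline import run_pipeline

fix = synth.generate_fixtures(tempfile.mkdtemp())
gaz   = G.Gazetteer.from_csv(fix["gazetteer"])
junk  = G.JunkLocationLibrary.from_file(fix["junk"])
polys = G.StatePolygons.from_geojson(fix["states"])
areas = M.UrbanAreas.from_geojson(fix["urban"])
lex   = S.augment_emoji(S.load_lexicon(fix["lexicon"]), fix["emoji"])

records, truth = synth.generate_corpus(synth.GeneratorConfig(n_tweets=5000, seed=11))
df, report = run_pipeline(records, gaz, junk, polys, areas, lex)
```

prints, with the derived quantities below:

```
kept 1007/5050 (retweets 2031, urls 2002, dupes 10)
geolocated to a US state: 27.81%
negative share among polar posts: 56.58%
quantile  n_metro  n_nonmetro  mean_metro  mean_nonmetro  p_value
     ALL      194          85     -0.0312        -0.0550   0.8239
      Q1       50          23     -0.6963        -0.6351   0.0646
      Q2       45          22     -0.3514        -0.3464   0.8048
      Q3       52          19      0.2559         0.2422   0.7306
      Q4       47          21      0.6653         0.6166   0.2295
example score: 0.5719 POSITIVE
```

Reading it: of 5,050 generated posts, 1,007 survive the structural filters
(reposts, URLs, duplicates); 27.81% resolve to a US state; among posts with
a polarity, 56.58% are negative. The table is the national slice of the
metro-vs-nonmetro harness — group sizes, group means and the Mann-Whitney
p-value per quartile stratum of the pooled scores (at these small n no
stratum reaches α = 0.001). The last line scores one post: "The nurse was
wonderful." gives a strongly positive compound, "Long wait though." carries
no lexicon term and contributes nothing, so the post is POSITIVE at 0.5719.

A `carepulse` console script exposes the same stages
(`carepulse synth fixtures`, `carepulse ingest`, `carepulse geoloc`,
`carepulse sentiment`, `carepulse metro`, `carepulse temporal`,
`carepulse stats`, `carepulse relevance train|predict`).

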