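# Methods

`emospect` re-implements, as a tested pipeline, an ontology-based emotion
and sentiment analysis of patient medication reviews for the three PDE5
inhibitors (sildenafil, vardenafil, tadalafil). The original study corpus
was scraped from medication-rating sites and is not publicly deposited, so
the package pairs the analysis code with a synthetic-corpus generator whose
ground truth makes every stage testable.

## Emotion lexicon and annotation

Emotions follow the Parrott taxonomy: six primary emotions (joy, love,
surprise, sadness, fear, anger), each branching into secondary and tertiary
classes that carry synonym lists. The packaged demonstration lexicon has 27
subclasses and 86 synonyms; it is illustrative, not a reconstruction of any
particular resource, and any lexicon in the same YAML schema can be loaded
in its place. Validation enforces the tree shape (every secondary under
exactly one primary, every tertiary under exactly one secondary) and
rejects any surface form that maps to two classes — no disambiguation rule
exists, so ambiguity fails loudly rather than silently resolving.

Annotation is gazetteer lookup over cleaned tokens. Both the lexicon
entries and the review text pass through the same normalizer (lowercase,
tokenize, rule-based suffix lemmatizer), so dictionary and text meet in one
canonical space; the lemmatizer is a small deterministic suffix stripper
(plural/-ing/-ed rules with an exception list), written for idempotence
rather than linguistic completeness. Candidate matches are all token
n-grams present in the term index; overlaps resolve longest-span-first with
leftmost tie-breaking, the standard gazetteer convention. Matching is
deliberately presence-only and negation-blind ("not happy" still annotates
joy): the profile is a detector of expressed emotion vocabulary, and
polarity belongs to the sentiment scorer. Per review the output is a
6-dimensional binary profile (emotions are non-exclusive) plus match
counts.

## Cleaning profiles

Two profiles exist because one cleaning cannot serve both consumers.
The *annotation* profile applies the full treatment (URL and number
removal, lowercasing, packaged stopword list, lemmatization). The
*sentiment* profile removes URLs only: the scorer's negators ("not",
"never") and boosters ("very") are exactly the words a stopword list
deletes. The stopword list is packaged and versioned in the repo; "down"
is deliberately excluded from it so multiword terms like "let down"
survive. A spellcheck hook exists but defaults off — third-party spellers
are version-unstable and would break determinism.

Age banding uses "<44" (meaning <=44, so the bands partition), "45-64" and
">=65"; durations band as short (<1 month), mid (1 month to <1 year) and
long (>=1 year). Ratings on a 10-point scale standardize to 5 points by
ceiling(raw/2), which preserves integer levels and both endpoints.

## Sentiment

The compound score implements the core of the classic social-media valence
heuristic: a signed valence dictionary, booster increments added to the
magnitude of the following valence term, polarity flipped when a negator
occurs within the 3 preceding tokens, and the bounded normalization
`compound = raw / sqrt(raw^2 + alpha)` with `alpha = 15` (configurable).
Punctuation/capitalization emphasis and contrastive-conjunction
reweighting are intentionally omitted to keep the component small and
exactly testable; an adapter slot accepts any external `text -> compound`
scorer for full-fidelity runs. The packaged valence lexicon (~170 terms,
including a handful of low-magnitude terms so the generator can realize
fine-grained targets) is demo scale; larger lexica load from TSV.

## Statistics

* Prevalence tables report, per stratum level, the percent of reviews
  expressing each emotion with SE `sqrt(p(1-p)/n)` on the proportion
  scale. One chi-square per stratifier is computed on the level x emotion
  mention-count contingency table (no continuity correction), mirroring a
  single-statistic-per-characteristic layout; statistically cleaner
  per-emotion presence x level chi-squares are emitted alongside.
* Per-emotion logistic regressions fit flag ~ drug + age band + duration
  band with references sildenafil / >=65 / short-term, reporting
  `OR = exp(beta)` with Wald 95% CIs (`z = 1.959964`), no small-sample or
  multiplicity correction. Separation and non-convergence raise named
  errors rather than returning unstable estimates.
* The sentiment model is OLS of the compound score on the six emotion
  flags plus drug, age, duration and rating year (continuous).
* Satisfaction is modeled twice on identical rows (listwise deletion for
  the union of both models' variables): with and without the sentiment
  term; the difference in unadjusted R-squared is the sentiment's
  incremental explanatory power and is non-negative by construction for
  nested least squares (adjusted values are also reported).

Model fitting is delegated to statsmodels (Logit/OLS) and scipy
(chi-square); the package owns design construction, reference coding,
listwise deletion, error taxonomy and reporting.

## Synthetic corpus generator

Reviews are token bags, not prose: text realism is sacrificed for
exactness, because the acceptance surface is statistical recovery. Each
review samples a stratum (drug x age band x duration band x year),
draws the six emotion flags from per-stratum logistic models, then builds
its text from (a) filler tokens validated to be disjoint from every
dictionary, (b) for each active emotion at least one surface form from
that emotion's branch of the lexicon, and (c) valence words greedily
selected so the summed valence realizes a target compound drawn from a
linear model on the flags and covariates plus Gaussian noise. Because
filler and valence words can never create emotion annotations, the
annotator's output equals the planted flags identically — the generator's
defining guarantee. Satisfaction is drawn from a linear model on the
target compound, rounded and clamped to the Likert scale (10-point for
the source emulating a 10-point site, chosen so standardization recovers
the 5-point value exactly); a continuous non-Likert mode exists for
analytic variance-decomposition checks. Randomness uses one stream per
review index derived from the corpus seed, so corpora are reproducible
independent of generation order.

Default parameters are the study-shaped conditions: 3070 reviews; drug
weights 973/406/1691; age, duration and rating-year marginals from the
study's corpus-description table (missing bands generated as their own
level with zero effect); emotion effects equal to the reported odds
ratios with intercepts solved numerically so population-average
prevalences match the reported pooled prevalences (joy 59.61%, sadness
34.14%, ...); sentiment coefficients equal to the reported betas
(joy +0.467 ... sadness -0.433) with noise sd 0.45, chosen by variance
arithmetic to land the regression R^2 near the reported 0.37; satisfaction
coefficients equal to the reported model (slope 0.97 per compound unit,
year centered at 2012) with noise sd 1.1, targeting an incremental R^2
near 0.19 before Likert discretization.

### What the generator does not emulate

Fluent language, sarcasm/irony, negated emotion mentions, rater behavior,
selection bias and temporal posting dynamics are all absent. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct under its own assumptions — not that the lexicon or scorer would
capture real reviews' emotions with any particular accuracy.

### Known distortions under the default conditions

Two deliberate realism features bias naive recovery and are left in place:

* The compound score is bounded in [-1, 1]; targets are clipped at ±0.95.
  Reviews combining several negative emotions sit near the boundary, so
  the unbounded linear sentiment model is misspecified there and fitted
  betas are attenuated/redistributed by roughly 10% under the default
  effect sizes. Recovery tests of the linear fit therefore use moderate
  planted effects (joy +0.45, sadness -0.40, others 0, noise sd 0.2) that
  stay well inside the bounds.
* Likert rounding and clamping of satisfaction attenuates the fitted
  sentiment slope (about 0.81 recovered for 0.97 planted) and the
  incremental R^2 (about 0.13 for a 0.19 target) relative to the
  continuous model — ordinary measurement coarsening, visible here only
  because the ground truth is known.

Logistic OR recovery additionally carries the usual small-sample MLE bias
away from the null; at 3000 complete cases it stays under about 7% for the
planted effects, but listwise deletion of the default missingness (which
removes nearly half the records) roughly doubles it for the smallest
terms. The recovery test batch therefore generates complete-case corpora.

## Pipeline and determinism

The orchestrated run deduplicates on (source, normalized text, drug) —
a conservative key that cannot merge distinct patients' different texts —
drops records that are empty after cleaning ("nontextual"), persists every
intermediate table, and emits a report whose hash is a pure function of
inputs, configuration and seed. All exclusions are counted and logged so
n-in/n-out accounting is mechanically auditable on any input.

## Problem sizes used by the test suite

Property tests use corpora of a few hundred reviews; recovery runs use 50
corpora of n = 3000; the Wald-coverage check uses 500 replicates of
n = 5000 single-covariate designs, a block chosen large enough that the
93% pass bound sits clearly below the interval's true coverage (~94%).
These sizes are the package's own choices balancing statistical resolution
against test-suite turnaround.
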