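# emospect

Ontology-based emotion and sentiment analysis of patient medication
reviews, built for the kind of pharmacovigilance question asked of the
PDE5 inhibitors (sildenafil, vardenafil, tadalafil): which of the six
Parrott primary emotions — joy, love, surprise, sadness, fear, anger —
do patients express about a drug, how do those emotions vary with age,
drug and duration of use, how much does each emotion drive the overall
sentiment of a review, and how much of the patient's satisfaction rating
does that sentiment explain?

The pipeline is: a 3-tier emotion lexicon (primary → secondary → tertiary
classes with synonyms) → text cleaning → gazetteer annotation to a binary
6-emotion profile per review → a rule-based compound sentiment score
`raw/√(raw²+15) ∈ (−1, 1)` → statistics:

* stratified prevalence `%` with SE `√(p(1−p)/n)` and chi-square tests;
* per-emotion logistic regressions, `OR = e^β` with Wald 95% CIs
  `e^{β ± 1.96·SE}` (references: sildenafil, age ≥65, short-term use);
* OLS of sentiment on the six emotion flags plus covariates;
* nested satisfaction models with and without sentiment on identical
  rows, reporting the increase in R² (ΔR²).

Because corpora of this kind are scraped and rarely redistributable, the
package includes a first-class synthetic corpus generator with known
ground truth: planted emotion terms, a valence-realized target compound
score and a satisfaction rating linearly linked to it. Its defining
guarantee is that the annotator recovers the planted emotion flags
exactly, which makes every downstream statistic testable against truth.

## Worked example

The numbered drivers under `analysis/` run the whole study shape on a
simulated corpus (n = 3070, seed 0), writing intermediates to `scratch/`
and tables to `results/`:

```
$ python analysis/01_simulate.py
generated 3070 reviews (seed 0) -> scratch/corpus/
planted prevalence (%): {'joy': 59.19, 'love': 18.47, 'surprise': 18.24,
                         'sadness': 33.26, 'fear': 14.72, 'anger': 5.18}

$ python analysis/02_annotate_score.py
annotated 3070 reviews; 3070 match the planted flags exactly
compound |error| mean 0.0053, max 0.0256

$ python analysis/03_statistics.py
pooled prevalence (%): {'joy': 59.19, ..., 'anger': 5.18}
sadness ~ tadalafil OR 4.30 (3.31-5.58)
sentiment R2 0.398; joy beta 0.440; sadness beta -0.376
satisfaction R2 0.11147 -> 0.24154, delta 0.13007
```

Reading the output: every annotated profile equals its planted truth
(the generator guarantee); the scored compounds track their targets to
±0.03. The logistic fit recovers the planted sadness–tadalafil odds
ratio (3.85) within its CI; joy and sadness dominate the sentiment
regression with opposite signs; and adding sentiment to the satisfaction
model raises R² by 0.13 — attenuated from the planted continuous-scale
value because the rating is a clamped 1–5 Likert score (see
`docs/methods.md` for why, and for every default parameter).

The same machinery is available as a CLI:

```
emospect simulate --seed 1 --n 500 --out out/
emospect run --config run.yaml
emospect validate-lexicon            # manifest of the packaged lexicon
emospect report --in out/
```

and as a library (`emospect.lexicon`, `.preprocess`, `.annotate`,
`.sentiment`, `.stats`, `.simulate`, `.pipeline`).

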