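"""The analytic layer over the annotated corpus: stratified prevalence with
chi-square tests, per-emotion logistic odds ratios, the sentiment-on-emotions
regression, and the nested satisfaction models with delta R^2.

Reads the scratch/ intermediates (run 01 and 02 first) and writes the result
tables under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from emospect.annotate import EmotionProfile
from emospect.io import read_reviews
from emospect.lexicon import PRIMARY_EMOTIONS
from emospect.pipeline import analyze, summarize_corpus
from emospect.sentiment import SentimentScore

ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    records = read_reviews(os.path.join(ROOT, "scratch", "corpus", "reviews.csv"))
    prof_df = pd.read_csv(os.path.join(ROOT, "scratch", "profiles.csv"))
    sent_df = pd.read_csv(os.path.join(ROOT, "scratch", "sentiments.csv"))
    profiles = [
        EmotionProfile(row["review_id"],
                       {e: int(row[e]) for e in PRIMARY_EMOTIONS},
                       {e: int(row[e]) for e in PRIMARY_EMOTIONS})
        for _, row in prof_df.iterrows()
    ]
    sentiments = [SentimentScore(r["review_id"], float(r["compound"]), float("nan"))
                  for _, r in sent_df.iterrows()]
    keep = {p.review_id for p in profiles}
    records = [r for r in records if r.review_id in keep]

    prevalence, logistic, sent_reg, satisfaction = analyze(records, profiles, sentiments)
    bundle = {
        "corpus_summary": summarize_corpus(records),
        "prevalence": prevalence,
        "logistic": logistic,
        "sentiment_regression": sent_reg,
        "satisfaction": satisfaction,
    }
    out = os.path.join(ROOT, "results", "03_statistics.json")
    with open(out, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)

    print("pooled prevalence (%):",
          {e: round(prevalence["pooled"]["percent"][f"all|{e}"], 2) for e in PRIMARY_EMOTIONS})
    sad = logistic["sadness"]["terms"]["drug[tadalafil]"]
    print("sadness ~ tadalafil OR %.2f (%.2f-%.2f)" % (sad["or"], sad["ci_low"], sad["ci_high"]))
    print("sentiment R2 %.3f; joy beta %.3f; sadness beta %.3f"
          % (sent_reg["r_squared"], sent_reg["terms"]["joy"]["beta"],
             sent_reg["terms"]["sadness"]["beta"]))
    print("satisfaction R2 %.5f -> %.5f, delta %.5f"
          % (satisfaction["r2_without"], satisfaction["r2_with"], satisfaction["delta_r2"]))
    print("wrote", out)


if __name__ == "__main__":
    main()
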