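"""Generate the study-shaped synthetic review corpus.

Emits the full corpus (reviews + ground truth) under scratch/corpus/ and a
small summary of the planted structure under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np

from emospect.io import write_reviews_csv
from emospect.lexicon import PRIMARY_EMOTIONS
from emospect.simulate import GeneratorConfig, generate_corpus

SEED = 0
ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    cfg = GeneratorConfig(n_reviews=3070, seed=SEED)
    records, truth = generate_corpus(cfg)

    corpus_dir = os.path.join(ROOT, "scratch", "corpus")
    os.makedirs(corpus_dir, exist_ok=True)
    write_reviews_csv(records, os.path.join(corpus_dir, "reviews.csv"))
    with open(os.path.join(corpus_dir, "ground_truth.json"), "w") as fh:
        json.dump({"flags": truth.flags, "compound_target": truth.compound_target,
                   "satisfaction_mean": truth.satisfaction_mean}, fh)

    summary = {
        "seed": SEED,
        "n_reviews": len(records),
        "n_per_drug": {d: sum(r.drug == d for r in records)
                       for d in ("sildenafil", "vardenafil", "tadalafil")},
        "planted_prevalence_pct": {
            emo: round(100 * float(np.mean([truth.flags[r.review_id][emo] for r in records])), 2)
            for emo in PRIMARY_EMOTIONS
        },
    }
    results = os.path.join(ROOT, "results")
    os.makedirs(results, exist_ok=True)
    with open(os.path.join(results, "01_simulation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    print(f"generated {len(records)} reviews (seed {SEED}) -> scratch/corpus/")
    print("planted prevalence (%):", summary["planted_prevalence_pct"])


if __name__ == "__main__":
    main()
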