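"""End-to-end orchestration: ingest -> preprocess -> annotate -> score ->
analyze, with persisted intermediates and a reproducible report.

Exclusion accounting mirrors the published workflow's style: duplicate
reviews (same source + normalized text + drug) and reviews that are empty
after cleaning ("nontextual") are dropped, and every exclusion is counted
in the report so the n-in / n-out bookkeeping is mechanically auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import EmotionProfile, annotate_corpus
from .io import read_reviews, write_reviews_csv
from .lexicon import PRIMARY_EMOTIONS, EmotionLexicon, default_lexicon, load_lexicon, validate_lexicon
from .preprocess import ReviewRecord, text_stats
from .sentiment import SentimentScore, load_valence_lexicon, score_corpus
from .simulate import GeneratorConfig, generate_corpus
from . import stats as st

__all__ = ["RunConfig", "RunReport", "run", "summarize_corpus", "dedupe"]

log = logging.getLogger(__name__)

_YEAR_BANDS = (("2001-2009", 2001, 2009), ("2010-2019", 2010, 2019), ("2020-2022", 2020, 2022))


@dataclass
class RunConfig:
    """Exactly one of ``reviews_path`` / ``simulate`` must be given."""

    reviews_path: Optional[str] = None
    simulate: Optional[GeneratorConfig] = None
    lexicon_path: Optional[str] = None
    valence_paths: Optional[tuple[str, str, str]] = None  # valence, boosters, negators
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if (self.reviews_path is None) == (self.simulate is None):
            raise ValueError("exactly one of reviews_path / simulate must be set")


@dataclass
class RunReport:
    n_input: int
    n_duplicates: int
    n_empty: int
    n_analyzed: int
    corpus_summary: dict
    prevalence: dict
    logistic: dict
    sentiment_regression: dict
    satisfaction: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_duplicates": self.n_duplicates,
            "n_empty": self.n_empty,
            "n_analyzed": self.n_analyzed,
            "corpus_summary": self.corpus_summary,
            "prevalence": self.prevalence,
            "logistic": self.logistic,
            "sentiment_regression": self.sentiment_regression,
            "satisfaction": self.satisfaction,
            "provenance": self.provenance,
        }

    def hash(self) -> str:
        """Content hash of everything except machine-local provenance."""
        d = self.to_dict()
        d["provenance"] = {k: v for k, v in d["provenance"].items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _norm_text(text: str) -> str:
    return " ".join(text.lower().split())


def dedupe(records: Sequence[ReviewRecord]) -> tuple[list[ReviewRecord], int]:
    """Drop exact duplicates on (source, normalized text, drug), keeping the
    first occurrence."""
    seen: set[tuple[str, str, str]] = set()
    out: list[ReviewRecord] = []
    dropped = 0
    for rec in records:
        key = (rec.source, _norm_text(rec.text), rec.drug)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(rec)
    return out, dropped


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return float("nan"), float("nan")
    arr = np.asarray(values, float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def summarize_corpus(records: Sequence[ReviewRecord]) -> dict:
    """Corpus-description table: per-drug counts and percentages for age,
    duration and year bands, plus mean (SD) satisfaction, characters and
    sentences."""
    drugs = ("sildenafil", "vardenafil", "tadalafil")
    out: dict = {"n_total": len(records), "n_per_drug": {}, "age": {}, "duration": {}, "year": {}}
    by_drug = {d: [r for r in records if r.drug == d] for d in drugs}
    for d in drugs:
        out["n_per_drug"][d] = len(by_drug[d])

    def _pct_block(level_of, levels):
        block = {}
        for lv in levels:
            row = {}
            for d in drugs:
                n = len(by_drug[d])
                k = sum(1 for r in by_drug[d] if level_of(r) == lv)
                row[d] = {"n": k, "pct": 100.0 * k / n if n else float("nan")}
            k_all = sum(row[d]["n"] for d in drugs)
            row["total"] = {
                "n": k_all,
                "pct": 100.0 * k_all / len(records) if records else float("nan"),
            }
            block[lv] = row
        return block

    out["age"] = _pct_block(lambda r: r.age_band or "missing", ("<44", "45-64", ">=65", "missing"))
    out["duration"] = _pct_block(
        lambda r: r.duration_band or "missing", ("short", "mid", "long", "missing")
    )

    def _year_band(r):
        if r.rating_year is None:
            return "missing"
        for name, lo, hi in _YEAR_BANDS:
            if lo <= r.rating_year <= hi:
                return name
        return "other"

    out["year"] = _pct_block(_year_band, tuple(b[0] for b in _YEAR_BANDS))

    sat = {}
    for d in drugs:
        sat[d] = _mean_sd([r.satisfaction_5 for r in by_drug[d] if r.satisfaction_5 is not None])
    sat["total"] = _mean_sd([r.satisfaction_5 for r in records if r.satisfaction_5 is not None])
    out["satisfaction_mean_sd"] = {k: {"mean": m, "sd": s} for k, (m, s) in sat.items()}

    stats_cs = {d: [text_stats(r.text) for r in by_drug[d]] for d in drugs}
    stats_cs["total"] = [text_stats(r.text) for r in records]
    out["characters_mean_sd"] = {
        k: dict(zip(("mean", "sd"), _mean_sd([c for c, _ in v]))) for k, v in stats_cs.items()
    }
    out["sentences_mean_sd"] = {
        k: dict(zip(("mean", "sd"), _mean_sd([s for _, s in v]))) for k, v in stats_cs.items()
    }
    return out


def _regression_dict(res: st.RegressionResult) -> dict:
    return {
        "model_id": res.model_id,
        "n_used": res.n_used,
        "r_squared": res.r_squared,
        "adj_r_squared": res.adj_r_squared,
        "reference_levels": res.reference_levels,
        "terms": {
            name: {
                "beta": t.beta,
                "se": t.se,
                "p": t.p,
                **({"or": t.odds_ratio, "ci_low": t.ci_low, "ci_high": t.ci_high}
                   if t.odds_ratio is not None
                   else {"ci_low": t.ci_low, "ci_high": t.ci_high}),
            }
            for name, t in res.terms.items()
        },
    }


def analyze(
    records: list[ReviewRecord],
    profiles: list[EmotionProfile],
    sentiments: list[SentimentScore],
) -> tuple[dict, dict, dict, dict]:
    """The statistics stage shared by run() and the analysis drivers."""
    prevalence = {}
    for strat in (None, "drug", "age_band", "duration_band"):
        tab = st.prevalence_table(profiles, records, stratifier=strat)
        prevalence[strat or "pooled"] = {
            "levels": list(tab.levels),
            "n": tab.n_per_level,
            "percent": {f"{lv}|{emo}": v for (lv, emo), v in tab.percent.items()},
            "se": {f"{lv}|{emo}": v for (lv, emo), v in tab.se.items()},
            "chi_square": tab.chi_square,
            "dof": tab.dof,
            "p_value": tab.p_value,
            "per_emotion_tests": tab.per_emotion_tests,
        }
    logistic = {}
    for emo in PRIMARY_EMOTIONS:
        try:
            logistic[emo] = _regression_dict(st.fit_emotion_logit(profiles, records, emo))
        except st.StatsInputError as exc:
            logistic[emo] = {"error": str(exc)}
    sent_reg = _regression_dict(st.fit_sentiment_on_emotions(profiles, sentiments, records))
    delta, m1, m2 = st.fit_satisfaction_models(records, sentiments)
    satisfaction = {
        "model1": _regression_dict(m1),
        "model2": _regression_dict(m2),
        "r2_with": delta.r2_with,
        "r2_without": delta.r2_without,
        "delta_r2": delta.delta,
        "adj_r2_with": delta.adj_r2_with,
        "adj_r2_without": delta.adj_r2_without,
    }
    return prevalence, logistic, sent_reg, satisfaction


def run(config: RunConfig) -> RunReport:
    """Execute all stages in order; deterministic given config + seed."""
    config.validate()
    lex = load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    manifest = validate_lexicon(lex)
    vlex = load_valence_lexicon(*config.valence_paths) if config.valence_paths else None

    if config.simulate is not None:
        records, _truth = generate_corpus(config.simulate, lexicon=lex)
    else:
        records = read_reviews(config.reviews_path)
    n_input = len(records)

    records, n_dup = dedupe(records)
    profiles, skipped = annotate_corpus(records, lex)
    skipped_set = set(skipped)
    analyzed = [r for r in records if r.review_id not in skipped_set]
    log.info("input %d, duplicates %d, empty/nontextual %d, analyzed %d",
             n_input, n_dup, len(skipped), len(analyzed))
    sentiments = score_corpus(analyzed, vlex)

    prevalence, logistic, sent_reg, satisfaction = analyze(analyzed, profiles, sentiments)

    cfg_for_hash = {
        "reviews_path": config.reviews_path,
        "simulate": config.simulate.to_dict() if config.simulate else None,
        "lexicon_path": config.lexicon_path,
        "seed": config.seed,
    }
    report = RunReport(
        n_input=n_input,
        n_duplicates=n_dup,
        n_empty=len(skipped),
        n_analyzed=len(analyzed),
        corpus_summary=summarize_corpus(analyzed),
        prevalence=prevalence,
        logistic=logistic,
        sentiment_regression=sent_reg,
        satisfaction=satisfaction,
        provenance={
            "software_version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_for_hash, sort_keys=True).encode()
            ).hexdigest(),
            "lexicon_manifest": {
                "n_subclasses": manifest.n_subclasses,
                "n_synonyms": manifest.n_synonyms,
            },
            "out_dir": config.out_dir,
        },
    )

    if config.out_dir:
        _persist(config.out_dir, analyzed, profiles, sentiments, report)
    return report


def _persist(out_dir, records, profiles, sentiments, report: RunReport) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_reviews_csv(records, os.path.join(out_dir, "reviews.csv"))
    pd.DataFrame(
        [
            {"review_id": p.review_id,
             **{f"{e}_flag": p.flags[e] for e in PRIMARY_EMOTIONS},
             **{f"{e}_n": p.n_matches[e] for e in PRIMARY_EMOTIONS}}
            for p in profiles
        ]
    ).to_csv(os.path.join(out_dir, "profiles.csv"), index=False)
    pd.DataFrame(
        [{"review_id": s.review_id, "compound": s.compound} for s in sentiments]
    ).to_csv(os.path.join(out_dir, "sentiments.csv"), index=False)
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    _write_tables(out_dir, report)


def _write_tables(out_dir, report: RunReport) -> None:
    """TSV mirrors of the prevalence and regression tables."""
    for strat, tab in report.prevalence.items():
        path = os.path.join(out_dir, f"prevalence_{strat}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("level\tn\t" + "\t".join(PRIMARY_EMOTIONS) + "\n")
            for lv in tab["levels"]:
                cells = [
                    f"{tab['percent'][f'{lv}|{emo}']:.2f} ({tab['se'][f'{lv}|{emo}']:.3f})"
                    for emo in PRIMARY_EMOTIONS
                ]
                fh.write(f"{lv}\t{tab['n'][lv]}\t" + "\t".join(cells) + "\n")
    with open(os.path.join(out_dir, "odds_ratios.tsv"), "w", encoding="utf-8") as fh:
        fh.write("term\t" + "\t".join(PRIMARY_EMOTIONS) + "\n")
        all_terms: list[str] = []
        for emo in PRIMARY_EMOTIONS:
            for term in report.logistic.get(emo, {}).get("terms", {}):
                if term != "Intercept" and term not in all_terms:
                    all_terms.append(term)
        for term in all_terms:
            cells = []
            for emo in PRIMARY_EMOTIONS:
                t = report.logistic.get(emo, {}).get("terms", {}).get(term)
                cells.append(f"{t['or']:.2f} ({t['ci_low']:.2f}-{t['ci_high']:.2f})" if t else "-")
            fh.write(term + "\t" + "\t".join(cells) + "\n")
    with open(os.path.join(out_dir, "sentiment_regression.tsv"), "w", encoding="utf-8") as fh:
        fh.write("term\tbeta\tse\tp\n")
        for name, t in report.sentiment_regression["terms"].items():
            fh.write(f"{name}\t{t['beta']:.3f}\t{t['se']:.3f}\t{t['p']:.4g}\n")
        fh.write(f"R2\t{report.sentiment_regression['r_squared']:.4f}\t\t\n")
    with open(os.path.join(out_dir, "satisfaction_models.tsv"), "w", encoding="utf-8") as fh:
        fh.write("term\tmodel1_beta\tmodel1_p\tmodel2_beta\tmodel2_p\n")
        m1t = report.satisfaction["model1"]["terms"]
        m2t = report.satisfaction["model2"]["terms"]
        for name in m1t:
            b1, p1 = m1t[name]["beta"], m1t[name]["p"]
            if name in m2t:
                fh.write(f"{name}\t{b1:.3f}\t{p1:.4g}\t{m2t[name]['beta']:.3f}\t{m2t[name]['p']:.4g}\n")
            else:
                fh.write(f"{name}\t{b1:.3f}\t{p1:.4g}\t-\t-\n")
        fh.write(
            f"R2\t{report.satisfaction['r2_with']:.5f}\t\t{report.satisfaction['r2_without']:.5f}\t\n"
        )
        fh.write(f"delta_R2\t{report.satisfaction['delta_r2']:.5f}\t\t\t\n")
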