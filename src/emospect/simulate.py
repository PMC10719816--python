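"""Synthetic review-corpus generator with known ground truth.

The generator emits token-bag "reviews" whose statistical structure is the
one the analysis pipeline assumes: stratified records (drug x age band x
duration band x year), per-stratum logistic emotion flags, planted emotion
terms drawn from the matching lexicon branch, planted valence words whose
summed valence realizes a target compound score, and a Likert satisfaction
rating linearly linked to sentiment.  Text realism is deliberately
sacrificed for exactness: with a filler vocabulary disjoint from every
dictionary, the annotator's output equals the planted flags identically,
which is the generator's defining guarantee.

Default parameters mirror the marginal structure and effect sizes of the
published PDE5-inhibitor review study this pipeline re-implements: drug
proportions 973/406/1691, band frequencies from its corpus table, emotion
effects equal to its reported odds ratios, sentiment coefficients equal to
its reported betas, and a satisfaction slope of 0.97 per compound unit.
Per-emotion intercepts were solved numerically so the population-average
prevalences match the reported pooled prevalences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .lexicon import EmotionLexicon, PRIMARY_EMOTIONS, default_lexicon, normalize_term
from .preprocess import ReviewRecord, lemmatize
from .sentiment import DEFAULT_ALPHA, ValenceLexicon, default_valence_lexicon
from .stats import standardize_satisfaction

__all__ = ["GeneratorConfig", "GroundTruth", "ConfigError", "generate_corpus", "roundtrip_check", "default_config"]


class ConfigError(ValueError):
    """Invalid generator configuration."""


_DEFAULT_FILLER = (
    "tablet dose doctor pill morning evening week month pharmacy prescription "
    "insurance water food dinner routine schedule refill bottle label generic "
    "brand capsule daily nightly weekend supply order shipment clinic nurse "
    "visit checkup chart note form paper desk phone call email"
).split()

_LN = math.log

_DEFAULT_EMOTION_MODEL = {
    # intercepts solved so population-average prevalence over the default
    # strata hits the pooled targets (joy 59.61%, love 18.93%, surprise
    # 17.06%, sadness 34.14%, fear 14.50%, anger 5.60%)
    "joy": {"intercept": -0.1019, "drug": {"vardenafil": _LN(1.15), "tadalafil": _LN(1.12)},
            "age_band": {"<44": _LN(1.69), "45-64": _LN(1.54)},
            "duration_band": {"mid": _LN(1.40), "long": _LN(1.41)}},
    "love": {"intercept": -1.5425, "drug": {"vardenafil": _LN(0.95), "tadalafil": _LN(1.07)},
             "age_band": {"<44": _LN(1.05), "45-64": _LN(1.03)},
             "duration_band": {"mid": _LN(1.06), "long": _LN(1.11)}},
    "surprise": {"intercept": -1.6625, "drug": {"vardenafil": _LN(0.75), "tadalafil": _LN(0.79)},
                 "age_band": {"<44": _LN(2.00), "45-64": _LN(1.49)},
                 "duration_band": {"mid": _LN(0.90), "long": _LN(0.82)}},
    "sadness": {"intercept": -1.6333, "drug": {"vardenafil": _LN(1.06), "tadalafil": _LN(3.85)},
                "age_band": {"<44": _LN(1.86), "45-64": _LN(1.98)},
                "duration_band": {"mid": _LN(0.49), "long": _LN(0.61)}},
    "fear": {"intercept": -1.5908, "drug": {"vardenafil": _LN(0.49), "tadalafil": _LN(0.71)},
             "age_band": {"<44": _LN(2.25), "45-64": _LN(1.28)},
             "duration_band": {"mid": _LN(0.72), "long": _LN(0.51)}},
    "anger": {"intercept": -2.8488, "drug": {"vardenafil": _LN(1.06), "tadalafil": _LN(1.22)},
              "age_band": {"<44": _LN(1.07), "45-64": _LN(0.93)},
              "duration_band": {"mid": _LN(0.74), "long": _LN(0.91)}},
}

_DEFAULT_SENTIMENT_MODEL = {
    "intercept": -0.16,
    "emotions": {"joy": 0.467, "love": 0.249, "surprise": 0.287,
                 "sadness": -0.433, "fear": -0.139, "anger": -0.114},
    "drug": {"vardenafil": 0.0, "tadalafil": -0.067},
    "age_band": {},
    "duration_band": {"mid": 0.155, "long": 0.141},
    "year_slope": 0.005,
    "year_center": 2012,
    "noise_sd": 0.45,
}

_DEFAULT_SATISFACTION_MODEL = {
    "intercept": 3.0,
    "sentiment_slope": 0.97,
    "drug": {"vardenafil": -0.07, "tadalafil": 0.04},
    "age_band": {"<44": 0.32, "45-64": 0.26},
    "duration_band": {"mid": 0.43, "long": 0.57},
    "year_slope": 0.01,
    "year_center": 2012,
    "noise_sd": 1.1,
}


@dataclass
class GeneratorConfig:
    n_reviews: int = 3070
    seed: int = 0
    drug_weights: dict = field(default_factory=lambda: {
        "sildenafil": 973 / 3070, "vardenafil": 406 / 3070, "tadalafil": 1691 / 3070})
    age_weights: dict = field(default_factory=lambda: {
        "<44": 547 / 3070, "45-64": 1252 / 3070, ">=65": 361 / 3070, "missing": 910 / 3070})
    duration_weights: dict = field(default_factory=lambda: {
        "short": 1001 / 3070, "mid": 676 / 3070, "long": 665 / 3070, "missing": 728 / 3070})
    year_weights: dict = field(default_factory=lambda: {
        "2001-2009": 759 / 3070, "2010-2019": 2020 / 3070, "2020-2022": 291 / 3070})
    source_weights: dict = field(default_factory=lambda: {
        "webmd": 0.35, "askapatient": 0.25, "drugscom": 0.40})
    emotion_model: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EMOTION_MODEL.items()})
    sentiment_model: dict = field(default_factory=lambda: dict(_DEFAULT_SENTIMENT_MODEL))
    satisfaction_model: dict = field(default_factory=lambda: dict(_DEFAULT_SATISFACTION_MODEL))
    filler_vocab: tuple = tuple(_DEFAULT_FILLER)
    filler_tokens_range: tuple = (8, 25)
    max_valence_words: int = 20
    valence_tolerance: float = 0.05
    compound_clip: float = 0.95

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filler_vocab"] = list(self.filler_vocab)
        d["filler_tokens_range"] = list(self.filler_tokens_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "filler_vocab" in d:
            d["filler_vocab"] = tuple(d["filler_vocab"])
        if "filler_tokens_range" in d:
            d["filler_tokens_range"] = tuple(d["filler_tokens_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


@dataclass
class GroundTruth:
    """Planted per-review truth plus the generating configuration."""

    flags: dict  # review_id -> {emotion: 0/1}
    compound_target: dict  # review_id -> float
    satisfaction_mean: dict  # review_id -> float (pre-noise linear predictor)
    config: dict


def _validate(cfg: GeneratorConfig, lex: EmotionLexicon, vlex: ValenceLexicon) -> None:
    for name, w in [("drug_weights", cfg.drug_weights), ("age_weights", cfg.age_weights),
                    ("duration_weights", cfg.duration_weights), ("year_weights", cfg.year_weights),
                    ("source_weights", cfg.source_weights)]:
        vals = list(w.values())
        if any(v < 0 for v in vals) or not math.isclose(sum(vals), 1.0, abs_tol=1e-6):
            raise ConfigError(f"{name} must be a probability distribution, got {w}")
    lex_tokens = {tok for key in lex.term_index for tok in key}
    reserved = set(vlex.valences) | set(vlex.boosters) | vlex.negators
    for tok in cfg.filler_vocab:
        if lemmatize(tok.lower()) in lex_tokens:
            raise ConfigError(f"filler token {tok!r} collides with the emotion lexicon")
        if tok.lower() in reserved:
            raise ConfigError(f"filler token {tok!r} collides with the valence lexicon")
    # planted valence words must never create emotion annotations
    for term in vlex.valences:
        if normalize_term(term) in lex.term_index:
            raise ConfigError(f"valence term {term!r} collides with the emotion lexicon")
    for emo, model in cfg.emotion_model.items():
        if emo not in PRIMARY_EMOTIONS:
            raise ConfigError(f"unknown emotion {emo!r} in emotion_model")
        for grp in ("drug", "age_band", "duration_band"):
            for lv, eff in model.get(grp, {}).items():
                if not math.isfinite(eff):
                    raise ConfigError(f"non-finite effect for {emo}/{grp}/{lv}")
    max_raw = cfg.max_valence_words * max(abs(v) for v in vlex.valences.values())
    c = cfg.compound_clip
    need = c * math.sqrt(DEFAULT_ALPHA / (1 - c * c))
    if max_raw < need:
        raise ConfigError(
            f"packaged valence lexicon cannot reach compound {c} "
            f"(needs raw sum {need:.1f}, max achievable {max_raw:.1f})"
        )


def _emotion_surfaces(lex: EmotionLexicon) -> dict[str, list[str]]:
    """primary -> surface forms (labels and synonyms) of its branch."""
    out: dict[str, list[str]] = {p: [] for p in PRIMARY_EMOTIONS}
    for cls in lex.classes.values():
        prim = lex.primary_of(cls.label)
        out[prim].append(cls.label)
        out[prim].extend(cls.synonyms)
    return {p: sorted(set(v)) for p, v in out.items()}


def _plant_valence(target_raw: float, vlex: ValenceLexicon, rng: np.random.Generator,
                   max_words: int, tol: float) -> list[str]:
    """Greedy selection of valence words whose valences sum near target."""
    terms = sorted(vlex.valences)
    vals = np.array([vlex.valences[t] for t in terms])
    chosen: list[str] = []
    rem = target_raw
    for _ in range(max_words):
        if abs(rem) < tol:
            break
        idx = np.abs(vals - rem).argmin()
        if abs(rem - vals[idx]) >= abs(rem):
            break
        # among terms within 0.05 of the best valence, pick one at random
        near = np.flatnonzero(np.abs(vals - vals[idx]) < 0.05)
        pick = int(rng.choice(near))
        chosen.append(terms[pick])
        rem -= vals[pick]
    return chosen


def _sample_level(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


_YEAR_SPANS = {"2001-2009": (2001, 2009), "2010-2019": (2010, 2019), "2020-2022": (2020, 2022)}


def generate_corpus(
    config: GeneratorConfig,
    lexicon: Optional[EmotionLexicon] = None,
    valence: Optional[ValenceLexicon] = None,
) -> tuple[list[ReviewRecord], GroundTruth]:
    """Generate a corpus; fully reproducible from ``config.seed``.

    One sub-stream per review index keeps reproducibility independent of
    generation order.
    """
    lex = lexicon or default_lexicon()
    vlex = valence or default_valence_lexicon()
    _validate(config, lex, vlex)
    surfaces = _emotion_surfaces(lex)
    smod = config.sentiment_model
    tmod = config.satisfaction_model

    records: list[ReviewRecord] = []
    flags_gt: dict[str, dict[str, int]] = {}
    compound_gt: dict[str, float] = {}
    satmean_gt: dict[str, float] = {}

    for i in range(config.n_reviews):
        rng = np.random.default_rng([config.seed, i])
        rid = f"r{i:05d}"
        drug = _sample_level(rng, config.drug_weights)
        age_band = _sample_level(rng, config.age_weights)
        dur_band = _sample_level(rng, config.duration_weights)
        span = _YEAR_SPANS[_sample_level(rng, config.year_weights)]
        year = int(rng.integers(span[0], span[1] + 1))
        source = _sample_level(rng, config.source_weights)

        age_obs = None if age_band == "missing" else age_band
        dur_obs = None if dur_band == "missing" else dur_band

        # emotion flags from the per-stratum logistic model; one uniform per
        # emotion drawn before anything flag-dependent, so raising an
        # intercept can only switch flags 0 -> 1 at a fixed seed
        u = rng.random(len(PRIMARY_EMOTIONS))
        flags: dict[str, int] = {}
        for j, emo in enumerate(PRIMARY_EMOTIONS):
            m = config.emotion_model[emo]
            eta = m["intercept"]
            eta += m.get("drug", {}).get(drug, 0.0)
            eta += m.get("age_band", {}).get(age_obs, 0.0) if age_obs else 0.0
            eta += m.get("duration_band", {}).get(dur_obs, 0.0) if dur_obs else 0.0
            p = 1.0 / (1.0 + math.exp(-eta))
            flags[emo] = int(u[j] < p)

        # target compound from the planted linear model
        eta_s = smod["intercept"]
        for emo in PRIMARY_EMOTIONS:
            eta_s += smod["emotions"].get(emo, 0.0) * flags[emo]
        eta_s += smod.get("drug", {}).get(drug, 0.0)
        eta_s += smod.get("age_band", {}).get(age_obs, 0.0) if age_obs else 0.0
        eta_s += smod.get("duration_band", {}).get(dur_obs, 0.0) if dur_obs else 0.0
        eta_s += smod.get("year_slope", 0.0) * (year - smod.get("year_center", 2012))
        target = eta_s + rng.normal(0.0, smod["noise_sd"])
        target = float(np.clip(target, -config.compound_clip, config.compound_clip))

        # assemble text: filler + one or more terms per active emotion +
        # valence words realizing the target compound
        units: list[list[str]] = []
        k_filler = int(rng.integers(*config.filler_tokens_range))
        for tok in rng.choice(len(config.filler_vocab), size=k_filler):
            units.append([config.filler_vocab[int(tok)]])
        for emo in PRIMARY_EMOTIONS:
            if flags[emo]:
                n_terms = 1 + int(rng.random() < 0.3)
                for t in range(n_terms):
                    surf = surfaces[emo][int(rng.integers(len(surfaces[emo])))]
                    units.append(surf.split())
        raw_target = target * math.sqrt(DEFAULT_ALPHA / (1.0 - target * target))
        for term in _plant_valence(raw_target, vlex, rng, config.max_valence_words,
                                   config.valence_tolerance):
            units.append([term])
        rng.shuffle(units)
        tokens = [tok for unit in units for tok in unit]
        # sentence breaks every ~9 tokens
        parts = []
        for j, tok in enumerate(tokens):
            parts.append(tok)
            if (j + 1) % 9 == 0:
                parts[-1] = tok + "."
        text = " ".join(parts)
        if not text.endswith("."):
            text += "."

        # satisfaction from the planted linear model on the target compound
        mu = tmod["intercept"] + tmod["sentiment_slope"] * target
        mu += tmod.get("drug", {}).get(drug, 0.0)
        mu += tmod.get("age_band", {}).get(age_obs, 0.0) if age_obs else 0.0
        mu += tmod.get("duration_band", {}).get(dur_obs, 0.0) if dur_obs else 0.0
        mu += tmod.get("year_slope", 0.0) * (year - tmod.get("year_center", 2012))
        cont = mu + rng.normal(0.0, tmod["noise_sd"])
        likert = tmod.get("likert", True)
        if likert:
            raw5 = int(np.clip(math.floor(cont + 0.5), 1, 5))
            if source == "drugscom":
                scale = 10
                raw = raw5 * 2 - int(rng.integers(0, 2))  # both halves round back to raw5
            else:
                scale = 5
                raw = raw5
            sat5: float = float(standardize_satisfaction(raw, scale))
        else:
            # continuous satisfaction for analytic variance-decomposition checks
            scale, raw = 5, None
            sat5 = float(cont)

        dur_months = None
        if dur_obs == "short":
            dur_months = float(rng.uniform(0.1, 0.9))
        elif dur_obs == "mid":
            dur_months = float(rng.uniform(1.0, 11.5))
        elif dur_obs == "long":
            dur_months = float(rng.uniform(12.0, 60.0))

        records.append(
            ReviewRecord(
                review_id=rid,
                source=source,
                drug=drug,
                text=text,
                age=None,
                age_band=age_obs,
                duration_months=dur_months,
                duration_band=dur_obs,
                rating_year=year,
                satisfaction_raw=raw,
                satisfaction_scale=scale,
                satisfaction_5=sat5,
            )
        )
        flags_gt[rid] = flags
        compound_gt[rid] = target
        satmean_gt[rid] = mu

    truth = GroundTruth(
        flags=flags_gt,
        compound_target=compound_gt,
        satisfaction_mean=satmean_gt,
        config=config.to_dict(),
    )
    return records, truth


def roundtrip_check(config: GeneratorConfig) -> dict:
    """Run the full pipeline on a generated corpus; report planted vs recovered."""
    from .annotate import annotate_corpus
    from .sentiment import score_corpus
    from . import stats as st

    lex = default_lexicon()
    records, truth = generate_corpus(config, lexicon=lex)
    profiles, skipped = annotate_corpus(records, lex)
    sentiments = score_corpus(records)

    report: dict = {"n_reviews": len(records), "n_skipped": len(skipped)}

    prev = st.prevalence_table(profiles, records, stratifier=None)
    report["prevalence"] = {
        emo: {
            "planted_pct": 100.0 * np.mean([truth.flags[r.review_id][emo] for r in records]),
            "recovered_pct": prev.percent[("all", emo)],
        }
        for emo in PRIMARY_EMOTIONS
    }

    report["logistic"] = {}
    for emo in PRIMARY_EMOTIONS:
        res = st.fit_emotion_logit(profiles, records, emo)
        m = config.emotion_model[emo]
        terms = {}
        for grp in ("drug", "age_band", "duration_band"):
            for lv, eff in m.get(grp, {}).items():
                name = f"{grp}[{lv}]"
                t = res.terms.get(name)
                if t is not None:
                    terms[name] = {
                        "planted_or": math.exp(eff),
                        "recovered_or": t.odds_ratio,
                        "ci": (t.ci_low, t.ci_high),
                        "covered": t.ci_low <= math.exp(eff) <= t.ci_high,
                    }
        report["logistic"][emo] = terms

    sres = st.fit_sentiment_on_emotions(profiles, sentiments, records)
    report["sentiment_betas"] = {
        emo: {
            "planted": config.sentiment_model["emotions"][emo],
            "recovered": sres.terms[emo].beta,
            "ci": (sres.terms[emo].ci_low, sres.terms[emo].ci_high),
            "covered": sres.terms[emo].ci_low
            <= config.sentiment_model["emotions"][emo]
            <= sres.terms[emo].ci_high,
        }
        for emo in PRIMARY_EMOTIONS
    }
    report["sentiment_r2"] = sres.r_squared

    delta, m1, m2 = st.fit_satisfaction_models(records, sentiments)
    report["satisfaction"] = {
        "planted_slope": config.satisfaction_model["sentiment_slope"],
        "recovered_slope": m1.terms["sentiment"].beta,
        "r2_with": delta.r2_with,
        "r2_without": delta.r2_without,
        "delta_r2": delta.delta,
    }
    return report


def default_config(seed: int = 0, n_reviews: int = 3070) -> GeneratorConfig:
    """The packaged study-shaped configuration."""
    return GeneratorConfig(n_reviews=n_reviews, seed=seed)
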