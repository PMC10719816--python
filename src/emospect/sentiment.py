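"""Rule-based compound sentiment scoring in [-1, 1].

The scorer implements the core of the classic social-media valence
heuristic: a signed valence dictionary, booster words that amplify or
dampen the following valence term, a 3-token negation window that flips
polarity, and the bounded normalization

    compound = raw_sum / sqrt(raw_sum**2 + alpha),   alpha = 15.

Punctuation/capitalization emphasis and contrastive-conjunction
reweighting are intentionally omitted; an ``adapter`` hook accepts any
``text -> compound`` callable for full-fidelity external scorers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

from .preprocess import CleanText, ReviewRecord, clean

__all__ = [
    "ValenceLexicon",
    "SentimentScore",
    "load_valence_lexicon",
    "default_valence_lexicon",
    "score_sentiment",
    "score_corpus",
    "DEFAULT_ALPHA",
    "NEGATION_WINDOW",
]

DEFAULT_ALPHA = 15.0
NEGATION_WINDOW = 3


@dataclass(frozen=True)
class ValenceLexicon:
    valences: dict[str, float]
    boosters: dict[str, float]
    negators: frozenset[str]

    def __post_init__(self):
        bad = set(self.valences) & self.negators
        if bad:
            raise ValueError(f"negators must be disjoint from valence terms: {sorted(bad)}")
        for term, v in self.valences.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite valence for {term!r}")


@dataclass(frozen=True)
class SentimentScore:
    review_id: str
    compound: float
    raw_sum: float
    normalization_alpha: float = DEFAULT_ALPHA


def _read_tsv(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term, val = line.split("\t")
        out[term] = float(val)
    return out


def load_valence_lexicon(valence_path, booster_path, negator_path) -> ValenceLexicon:
    """TSV (term, valence) + TSV (booster, increment) + newline negator list."""
    with open(valence_path, encoding="utf-8") as fh:
        valences = _read_tsv(fh.read())
    with open(booster_path, encoding="utf-8") as fh:
        boosters = _read_tsv(fh.read())
    with open(negator_path, encoding="utf-8") as fh:
        negators = frozenset(w.strip() for w in fh if w.strip())
    return ValenceLexicon(valences=valences, boosters=boosters, negators=negators)


_DEFAULT: Optional[ValenceLexicon] = None


def default_valence_lexicon() -> ValenceLexicon:
    """The packaged mini valence lexicon (demo scale, ~170 terms)."""
    global _DEFAULT
    if _DEFAULT is None:
        data = resources.files("emospect.data")
        _DEFAULT = ValenceLexicon(
            valences=_read_tsv(data.joinpath("valence.tsv").read_text("utf-8")),
            boosters=_read_tsv(data.joinpath("boosters.tsv").read_text("utf-8")),
            negators=frozenset(
                w.strip()
                for w in data.joinpath("negators.txt").read_text("utf-8").splitlines()
                if w.strip()
            ),
        )
    return _DEFAULT


def normalize(raw_sum: float, alpha: float = DEFAULT_ALPHA) -> float:
    return raw_sum / math.sqrt(raw_sum * raw_sum + alpha)


def score_sentiment(
    ct: CleanText,
    vlex: Optional[ValenceLexicon] = None,
    review_id: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> SentimentScore:
    """Score the lightly cleaned token stream of one review.

    For each valence term: booster increments of the immediately
    preceding booster chain are added to |valence| (sign-aligned), then
    the polarity flips if any negator occurs within the 3 preceding
    tokens.
    """
    vlex = vlex or default_valence_lexicon()
    tokens = [t.lower() for t in ct.tokens_sentiment]
    raw = 0.0
    for i, tok in enumerate(tokens):
        v = vlex.valences.get(tok)
        if v is None:
            continue
        sign = 1.0 if v > 0 else -1.0
        j = i - 1
        while j >= 0 and tokens[j] in vlex.boosters:
            v += sign * vlex.boosters[tokens[j]]
            j -= 1
        if any(t in vlex.negators for t in tokens[max(0, i - NEGATION_WINDOW) : i]):
            v = -v
        raw += v
    return SentimentScore(
        review_id=review_id,
        compound=normalize(raw, alpha),
        raw_sum=raw,
        normalization_alpha=alpha,
    )


def score_corpus(
    reviews: list[ReviewRecord],
    vlex: Optional[ValenceLexicon] = None,
    alpha: float = DEFAULT_ALPHA,
    adapter: Optional[Callable[[str], float]] = None,
) -> list[SentimentScore]:
    """Batch scorer, order-preserving and deterministic.

    ``adapter``: optional external ``text -> compound`` scorer; when set
    it replaces the native rules but keeps the output contract.
    """
    out: list[SentimentScore] = []
    for rec in reviews:
        if adapter is not None:
            c = float(adapter(rec.text))
            out.append(SentimentScore(review_id=rec.review_id, compound=c, raw_sum=float("nan"), normalization_alpha=alpha))
            continue
        ct = clean(rec.text, profile="sentiment")
        out.append(score_sentiment(ct, vlex, review_id=rec.review_id, alpha=alpha))
    return out
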