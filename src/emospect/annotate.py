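"""Gazetteer annotation of emotion terms and per-review emotion profiles.

Matching runs over the fully cleaned (lemmatized) token sequence against
the lexicon's term index.  All candidate n-gram hits are collected and
overlaps are resolved longest-span-first with leftmost tie-breaking, the
standard gazetteer convention; surviving spans never overlap.

Negation is deliberately not handled ("not happy" still annotates joy):
the profile is a presence detector, not a polarity judge, and the
sentiment scorer owns polarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .lexicon import PRIMARY_EMOTIONS, EmotionLexicon
from .preprocess import CleanText, ReviewRecord, clean

__all__ = ["EmotionAnnotation", "EmotionProfile", "annotate", "profile", "annotate_corpus"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmotionAnnotation:
    """One matched term: half-open token span in ``tokens_annotation``."""

    review_id: str
    span: tuple[int, int]
    matched_term: str
    tertiary_class: str
    secondary_class: str
    primary_class: str


@dataclass(frozen=True)
class EmotionProfile:
    """Binary presence of each primary emotion plus match counts."""

    review_id: str
    flags: dict[str, int] = field(default_factory=dict)
    n_matches: dict[str, int] = field(default_factory=dict)

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.flags[p] for p in PRIMARY_EMOTIONS)


def annotate(ct: CleanText, lex: EmotionLexicon, review_id: str = "") -> list[EmotionAnnotation]:
    """Match lexicon terms in the cleaned token stream.

    Candidate spans are every n-gram (n up to the longest dictionary
    term) present in the term index; overlaps are resolved longest-first,
    ties leftmost.
    """
    tokens = ct.tokens_annotation
    if not tokens or not lex.term_index:
        return []
    candidates: list[tuple[int, int]] = []  # (start, end)
    maxlen = lex.max_term_len
    for start in range(len(tokens)):
        for n in range(1, min(maxlen, len(tokens) - start) + 1):
            if tokens[start : start + n] in lex.term_index:
                candidates.append((start, start + n))
    # longest span first, then leftmost
    candidates.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    taken = [False] * len(tokens)
    chosen: list[tuple[int, int]] = []
    for start, end in candidates:
        if any(taken[start:end]):
            continue
        for i in range(start, end):
            taken[i] = True
        chosen.append((start, end))
    chosen.sort()
    out = []
    for start, end in chosen:
        key = tokens[start:end]
        cls = lex.term_index[key]
        ter, sec, prim = lex.lineage(cls.label)
        out.append(
            EmotionAnnotation(
                review_id=review_id,
                span=(start, end),
                matched_term=" ".join(key),
                tertiary_class=ter,
                secondary_class=sec,
                primary_class=prim,
            )
        )
    return out


def profile(annotations: list[EmotionAnnotation], review_id: str) -> EmotionProfile:
    """Aggregate annotations into the 6-dimensional binary profile."""
    for ann in annotations:
        if ann.review_id != review_id:
            raise ValueError(
                f"annotation for {ann.review_id!r} mixed into profile of {review_id!r}"
            )
    counts = {p: 0 for p in PRIMARY_EMOTIONS}
    for ann in annotations:
        counts[ann.primary_class] += 1
    flags = {p: int(c >= 1) for p, c in counts.items()}
    return EmotionProfile(review_id=review_id, flags=flags, n_matches=counts)


def annotate_corpus(
    reviews: list[ReviewRecord],
    lex: EmotionLexicon,
    skip_empty: bool = True,
) -> tuple[list[EmotionProfile], list[str]]:
    """Clean + annotate + profile every review, order-preserving.

    Records whose text is empty after cleaning are skipped (their ids are
    returned in the second element); a record that fails outright is
    logged with its review_id and skipped rather than aborting the batch.
    """
    profiles: list[EmotionProfile] = []
    skipped: list[str] = []
    for rec in reviews:
        try:
            ct = clean(rec.text, profile="annotation")
            if skip_empty and not ct.tokens_annotation:
                skipped.append(rec.review_id)
                log.info("review %s: empty after cleaning, skipped", rec.review_id)
                continue
            anns = annotate(ct, lex, review_id=rec.review_id)
            profiles.append(profile(anns, rec.review_id))
        except Exception:  # noqa: BLE001 - per-record isolation is the contract
            skipped.append(rec.review_id)
            log.exception("review %s: annotation failed, skipped", rec.review_id)
    return profiles, skipped
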