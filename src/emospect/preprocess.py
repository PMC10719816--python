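"""Text cleaning, tokenization, lemmatization and record banding.

Two cleaning profiles are provided.  The *annotation* profile applies the
full treatment used before dictionary lookup of emotion terms: URL and
number removal, lowercasing, stopword removal and lemmatization.  The
*sentiment* profile only strips URLs, because the rule-based sentiment
scorer depends on negators ("not", "never", ...) and boosters ("very"),
which a stopword filter would destroy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

__all__ = [
    "CleanText",
    "ReviewRecord",
    "clean",
    "tokenize",
    "lemmatize",
    "split_sentences",
    "text_stats",
    "extract_age",
    "band_age",
    "band_duration",
    "load_stopwords",
    "AGE_BANDS",
    "DURATION_BANDS",
]

AGE_BANDS = ("<44", "45-64", ">=65")
DURATION_BANDS = ("short", "mid", "long")

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")
_DIGIT_RE = re.compile(r"\d")

# Terminal punctuation followed by whitespace/end splits sentences, except
# after a guarded abbreviation.
_ABBREV = {"mr", "mrs", "ms", "dr", "prof", "vs", "e.g", "i.e", "etc", "approx", "st"}
_SENT_RE = re.compile(r"[.!?]+(?=\s|$)")


@dataclass(frozen=True)
class CleanText:
    """Token views of one review under both cleaning profiles."""

    tokens_annotation: tuple[str, ...]
    tokens_sentiment: tuple[str, ...]
    sentences: tuple[str, ...]
    n_chars: int
    n_sentences: int


@dataclass
class ReviewRecord:
    """One patient medication review.

    ``age_band`` / ``duration_band`` use the closed label sets
    ``AGE_BANDS`` / ``DURATION_BANDS``; ``None`` encodes missing.
    ``satisfaction_raw`` is on the site's native 1-5 or 1-10 Likert scale
    (``satisfaction_scale``); ``satisfaction_5`` is the standardized 1-5
    value.
    """

    review_id: str
    source: str
    drug: str
    text: str
    age: Optional[int] = None
    age_band: Optional[str] = None
    duration_months: Optional[float] = None
    duration_band: Optional[str] = None
    rating_year: Optional[int] = None
    satisfaction_raw: Optional[int] = None
    satisfaction_scale: int = 5
    satisfaction_5: Optional[float] = None


_IRREGULAR = {
    "felt": "feel",
    "feet": "foot",
    "men": "man",
    "women": "woman",
    "children": "child",
    "teeth": "tooth",
    "was": "was",
    "has": "has",
    "is": "is",
    "this": "this",
    "his": "his",
    "does": "does",
    "went": "go",
    "better": "better",
    "best": "best",
    "worse": "worse",
    "worst": "worst",
}

_DOUBLE_UNSAFE = set("aeiou") | {"s", "l"}


def _undouble(stem: str) -> str:
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _DOUBLE_UNSAFE:
        return stem[:-1]
    return stem


def lemmatize(token: str) -> str:
    """Conservative rule-based suffix lemmatizer.

    Idempotent by construction (re-applying any rule output changes
    nothing); the same function normalizes lexicon entries and review
    tokens so both sides meet in one canonical space.
    """
    t = token
    if t in _IRREGULAR:
        return _IRREGULAR[t]
    if t.endswith("sses"):
        return t[:-2]
    if t.endswith("ies") and len(t) > 4:
        return t[:-3] + "y"
    if t.endswith("ss") or t.endswith("us") or t.endswith("is"):
        return t
    if t.endswith("s") and len(t) > 3:
        t = t[:-1]
    if t.endswith("ing") and len(t) > 5:
        return _undouble(t[:-3])
    if t.endswith("ed") and len(t) > 4:
        return _undouble(t[:-2])
    return t


def load_stopwords(path: Optional[str] = None) -> frozenset[str]:
    """Packaged stopword list (or an override file): one token per line."""
    if path is None:
        text = resources.files("emospect.data").joinpath("stopwords.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#"))


_DEFAULT_STOPWORDS: Optional[frozenset[str]] = None


def _default_stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords()
    return _DEFAULT_STOPWORDS


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation {. ! ?} + whitespace, guarding common
    abbreviations; unterminated trailing text counts as one sentence."""
    out: list[str] = []
    start = 0
    for m in _SENT_RE.finditer(text):
        candidate = text[start : m.start()]
        last = re.findall(r"[A-Za-z.]+$", candidate.strip())
        if last and last[0].rstrip(".").lower() in _ABBREV and m.group().startswith("."):
            continue
        if candidate.strip():
            out.append(candidate.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        out.append(tail)
    return out


def clean(
    text: str,
    profile: str = "annotation",
    stopwords: Optional[Iterable[str]] = None,
    spellcheck=None,
) -> CleanText:
    """Clean one review under the given profile.

    ``spellcheck`` is an optional pre-clean hook ``str -> str`` (default
    off, keeping runs deterministic).
    """
    if profile not in ("annotation", "sentiment"):
        raise ValueError(f"unknown cleaning profile: {profile!r}")
    raw = text
    if spellcheck is not None:
        text = spellcheck(text)
    no_url = _URL_RE.sub(" ", text)
    sentences = tuple(split_sentences(raw))

    sent_tokens = tuple(tokenize(no_url))

    sw = _default_stopwords() if stopwords is None else frozenset(stopwords)
    ann: list[str] = []
    for tok in tokenize(no_url.lower()):
        if _DIGIT_RE.search(tok):
            continue
        if tok in sw:
            continue
        lemma = lemmatize(tok)
        if lemma and lemma not in sw:
            ann.append(lemma)

    return CleanText(
        tokens_annotation=tuple(ann),
        tokens_sentiment=sent_tokens,
        sentences=sentences,
        n_chars=len(raw),
        n_sentences=len(sentences),
    )


def text_stats(text: str) -> tuple[int, int]:
    """(character count of the raw text, sentence count)."""
    return len(text), len(split_sentences(text))


# Age mention patterns: a number is only an age when anchored by an age cue,
# so bare doses ("100 mg") are rejected.
_AGE_PATTERNS = [
    re.compile(r"\b(\d{1,2})[\s-]*(?:years?|yrs?)[\s-]*old\b", re.IGNORECASE),
    re.compile(r"\b(\d{1,2})\s*(?:yo|y/o)\b", re.IGNORECASE),
    re.compile(r"\bage[d]?\s*(?:of\s*|:\s*)?(\d{1,2})\b", re.IGNORECASE),
    re.compile(r"\bi\s*am\s*(\d{1,2})\b(?!\s*(?:mg|mcg|ml|%))", re.IGNORECASE),
    re.compile(r"\bi'm\s*(\d{1,2})\b(?!\s*(?:mg|mcg|ml|%))", re.IGNORECASE),
]


def extract_age(text: str, lo: int = 18, hi: int = 99) -> Optional[int]:
    """First age matched by the documented pattern set, bounded to [lo, hi]."""
    hits: list[tuple[int, int]] = []
    for pat in _AGE_PATTERNS:
        for m in pat.finditer(text):
            age = int(m.group(1))
            if lo <= age <= hi:
                hits.append((m.start(), age))
    if not hits:
        return None
    return min(hits)[1]


def band_age(age: Optional[int]) -> Optional[str]:
    """Age banding; "<44" means <=44 so the bands partition the domain."""
    if age is None:
        return None
    if age <= 44:
        return "<44"
    if age <= 64:
        return "45-64"
    return ">=65"


def band_duration(months: Optional[float]) -> Optional[str]:
    """short: <1 month; mid: 1 month to <1 year; long: >=1 year."""
    if months is None:
        return None
    if months < 0:
        raise ValueError(f"negative duration: {months}")
    if months < 1:
        return "short"
    if months < 12:
        return "mid"
    return "long"
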