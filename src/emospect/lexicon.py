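"""Hierarchical (Parrott-style) emotion lexicon: load, validate, query.

The lexicon is a 3-tier tree — six fixed primary emotions, each branching
into secondary and tertiary classes — plus synonym lists attached to
non-primary classes.  It is serialized as YAML (one entry per class:
label, tier, parent, synonyms) rather than OWL; the schema carries all
the information the matching pipeline consumes.

Every class label and synonym is normalized with the same tokenizer and
lemmatizer used on review text, so dictionary and text meet in one
canonical space.  A surface form mapping to two different classes is a
hard validation error: no disambiguation rule is defined, so ambiguity
must fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .preprocess import lemmatize, tokenize

__all__ = [
    "PRIMARY_EMOTIONS",
    "EmotionClass",
    "EmotionLexicon",
    "LexiconManifest",
    "LexiconError",
    "LexiconSchemaError",
    "LexiconStructureError",
    "LexiconAmbiguityError",
    "load_lexicon",
    "save_lexicon",
    "validate_lexicon",
    "default_lexicon",
    "normalize_term",
]

#: Fixed order of the six primary emotions; downstream tables use it for
#: output columns.
PRIMARY_EMOTIONS = ("joy", "love", "surprise", "sadness", "fear", "anger")

TIERS = ("primary", "secondary", "tertiary")


class LexiconError(Exception):
    """Base class for lexicon problems."""


class LexiconSchemaError(LexiconError):
    """The file does not parse against the documented schema."""


class LexiconStructureError(LexiconError):
    """Orphan parents, cycles, tier violations."""


class LexiconAmbiguityError(LexiconError):
    """One surface form maps to two different classes."""


def normalize_term(term: str) -> tuple[str, ...]:
    """Lowercase, tokenize and lemmatize a dictionary entry."""
    return tuple(lemmatize(t) for t in tokenize(term.lower()))


@dataclass(frozen=True)
class EmotionClass:
    label: str
    tier: str
    parent: Optional[str] = None
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class LexiconManifest:
    """Recomputable summary counts for a loaded lexicon."""

    n_subclasses: int
    n_synonyms: int
    per_primary: dict[str, dict[str, int]] = field(default_factory=dict)


class EmotionLexicon:
    """Validated lexicon with a term index for gazetteer matching."""

    def __init__(self, classes: list[EmotionClass]):
        self.classes: dict[str, EmotionClass] = {}
        for cls in classes:
            if cls.label in self.classes:
                raise LexiconStructureError(f"duplicate class label {cls.label!r}")
            self.classes[cls.label] = cls
        self.primaries = PRIMARY_EMOTIONS
        self._check_structure()
        self.term_index: dict[tuple[str, ...], EmotionClass] = {}
        self._build_index()
        self.max_term_len = max((len(k) for k in self.term_index), default=0)

    # -- structure ---------------------------------------------------------
    def _check_structure(self) -> None:
        primaries = [c for c in self.classes.values() if c.tier == "primary"]
        labels = sorted(c.label for c in primaries)
        if labels != sorted(PRIMARY_EMOTIONS):
            raise LexiconStructureError(
                f"primary classes must be exactly {set(PRIMARY_EMOTIONS)}, got {set(labels)}"
            )
        for cls in self.classes.values():
            if cls.tier not in TIERS:
                raise LexiconStructureError(f"{cls.label!r}: unknown tier {cls.tier!r}")
            if (cls.tier == "primary") != (cls.parent is None):
                raise LexiconStructureError(
                    f"{cls.label!r}: tier {cls.tier} inconsistent with parent {cls.parent!r}"
                )
            if cls.parent is not None:
                parent = self.classes.get(cls.parent)
                if parent is None:
                    raise LexiconStructureError(
                        f"{cls.label!r}: parent {cls.parent!r} does not exist"
                    )
                want = {"secondary": "primary", "tertiary": "secondary"}[cls.tier]
                if parent.tier != want:
                    raise LexiconStructureError(
                        f"{cls.label!r} ({cls.tier}) must attach to a {want} class, "
                        f"but {cls.parent!r} is {parent.tier}"
                    )
        # parent tiers strictly decrease, so cycles cannot survive the tier
        # check; a defensive walk still guards hand-built class lists.
        for cls in self.classes.values():
            self.primary_of(cls.label)

    def _build_index(self) -> None:
        for cls in self.classes.values():
            entries = [cls.label] if cls.tier != "primary" else [cls.label]
            entries.extend(cls.synonyms)
            for surface in entries:
                key = normalize_term(surface)
                if not key or any(not tok for tok in key):
                    raise LexiconSchemaError(
                        f"{cls.label!r}: entry {surface!r} normalizes to an empty token"
                    )
                prev = self.term_index.get(key)
                if prev is not None and prev.label != cls.label:
                    raise LexiconAmbiguityError(
                        f"term {' '.join(key)!r} maps to both {prev.label!r} and {cls.label!r}"
                    )
                self.term_index[key] = cls

    # -- queries -----------------------------------------------------------
    def primary_of(self, class_label: str) -> str:
        """The unique primary ancestor (identity for primary labels)."""
        seen = set()
        label = class_label
        while True:
            cls = self.classes.get(label)
            if cls is None:
                raise KeyError(f"unknown emotion class {class_label!r}")
            if cls.tier == "primary":
                return cls.label
            if label in seen:
                raise LexiconStructureError(f"cycle through {label!r}")
            seen.add(label)
            label = cls.parent  # type: ignore[assignment]

    def lineage(self, class_label: str) -> tuple[str, str, str]:
        """(tertiary, secondary, primary) labels for a class; for a class
        attached at the second level, tertiary == secondary."""
        cls = self.classes[class_label]
        if cls.tier == "primary":
            return cls.label, cls.label, cls.label
        if cls.tier == "secondary":
            return cls.label, cls.label, self.primary_of(cls.label)
        sec = cls.parent
        return cls.label, sec, self.primary_of(cls.label)  # type: ignore[arg-type]


def validate_lexicon(lex: EmotionLexicon) -> LexiconManifest:
    """Recompute manifest counts; every invariant breach raises.

    Structure and ambiguity are already enforced at construction; this
    re-walks the tree so manifests stay honest for hand-mutated objects.
    """
    lex._check_structure()
    per_primary: dict[str, dict[str, int]] = {
        p: {"subclasses": 0, "synonyms": 0} for p in PRIMARY_EMOTIONS
    }
    n_sub = 0
    n_syn = 0
    for cls in lex.classes.values():
        if cls.tier == "primary":
            continue
        prim = lex.primary_of(cls.label)
        n_sub += 1
        n_syn += len(cls.synonyms)
        per_primary[prim]["subclasses"] += 1
        per_primary[prim]["synonyms"] += len(cls.synonyms)
    return LexiconManifest(n_subclasses=n_sub, n_synonyms=n_syn, per_primary=per_primary)


def _parse_entries(doc, origin: str) -> list[EmotionClass]:
    if not isinstance(doc, dict) or "classes" not in doc:
        raise LexiconSchemaError(f"{origin}: expected a mapping with a 'classes' list")
    entries = doc["classes"]
    if not isinstance(entries, list):
        raise LexiconSchemaError(f"{origin}: 'classes' must be a list")
    out = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict) or "label" not in entry or "tier" not in entry:
            raise LexiconSchemaError(f"{origin}: entry {i} needs 'label' and 'tier'")
        syns = entry.get("synonyms") or []
        if not isinstance(syns, list) or not all(isinstance(s, str) for s in syns):
            raise LexiconSchemaError(
                f"{origin}: entry {i} ({entry['label']!r}): 'synonyms' must be a list of strings"
            )
        out.append(
            EmotionClass(
                label=str(entry["label"]),
                tier=str(entry["tier"]),
                parent=entry.get("parent"),
                synonyms=tuple(syns),
            )
        )
    return out


def load_lexicon(path) -> EmotionLexicon:
    """Load and validate a YAML lexicon file."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LexiconSchemaError(f"{path}: not valid YAML: {exc}") from exc
    return EmotionLexicon(_parse_entries(doc, str(path)))


def loads_lexicon(text: str) -> EmotionLexicon:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise LexiconSchemaError(f"<string>: not valid YAML: {exc}") from exc
    return EmotionLexicon(_parse_entries(doc, "<string>"))


def save_lexicon(lex: EmotionLexicon, path) -> None:
    """Serialize back to the YAML schema (round-trips the term index)."""
    doc = {
        "classes": [
            {
                "label": c.label,
                "tier": c.tier,
                **({"parent": c.parent} if c.parent else {}),
                **({"synonyms": list(c.synonyms)} if c.synonyms else {}),
            }
            for c in lex.classes.values()
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_lexicon() -> EmotionLexicon:
    """The demonstration lexicon packaged with the library."""
    text = resources.files("emospect.data").joinpath("emotion_lexicon.yaml").read_text("utf-8")
    return loads_lexicon(text)
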