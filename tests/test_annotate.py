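"""Gazetteer matching, overlap resolution, and profile aggregation."""

import pytest
from hypothesis import given, settings, strategies as st

from emospect.annotate import annotate, annotate_corpus, profile
from emospect.lexicon import PRIMARY_EMOTIONS, EmotionClass, EmotionLexicon
from emospect.preprocess import CleanText, ReviewRecord, clean


def _ct(tokens):
    return CleanText(
        tokens_annotation=tuple(tokens),
        tokens_sentiment=tuple(tokens),
        sentences=(" ".join(tokens),),
        n_chars=len(" ".join(tokens)),
        n_sentences=1,
    )


def _lex(term_map):
    """term_map: class label -> (primary, synonyms) as a flat 2-tier lexicon."""
    classes = [EmotionClass(label=p, tier="primary") for p in PRIMARY_EMOTIONS]
    for label, (prim, syns) in term_map.items():
        classes.append(EmotionClass(label, "secondary", prim, tuple(syns)))
    return EmotionLexicon(classes)


class TestAnnotate:
    def test_out_of_lexicon_tokens_yield_nothing(self, lexicon):
        assert annotate(_ct(["tablet", "dissolve", "quickly"]), lexicon) == []

    def test_single_term_carries_lineage(self, lexicon):
        anns = annotate(_ct(["what", "delight"]), lexicon, review_id="r1")
        assert len(anns) == 1
        a = anns[0]
        assert (a.tertiary_class, a.secondary_class, a.primary_class) == (
            "delight", "cheerfulness", "joy")
        assert a.span == (1, 2)

    def test_longest_match_beats_component_terms(self, lexicon):
        # "let down" (dismay) must win over any shorter reading
        anns = annotate(_ct(["feel", "let", "down"]), lexicon)
        assert len(anns) == 1
        assert anns[0].matched_term == "let down"
        assert anns[0].span == (1, 3)
        assert anns[0].primary_class == "sadness"

    def test_matches_do_not_overlap(self, lexicon):
        toks = ["happy", "let", "down", "worry", "let", "down"]
        anns = annotate(_ct(toks), lexicon)
        spans = sorted(a.span for a in anns)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_raw_sentence_end_to_end(self, lexicon):
        ct = clean("I was so happy but then felt let down.", profile="annotation")
        prims = {a.primary_class for a in annotate(ct, lexicon)}
        assert prims == {"joy", "sadness"}


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

_VOCAB = [f"q{c}" for c in "abcdefgh"]


def _oracle(tokens, lex):
    """Independent matcher: enumerate every n-gram, keep lexicon hits,
    resolve overlaps longest-first then leftmost."""
    joined = {" ".join(k): cls for k, cls in lex.term_index.items()}
    maxn = max((len(k) for k in lex.term_index), default=0)
    hits = []
    for n in range(1, maxn + 1):
        for s in range(0, len(tokens) - n + 1):
            g = " ".join(tokens[s : s + n])
            if g in joined:
                hits.append((s, s + n, g))
    hits.sort(key=lambda h: (-(h[1] - h[0]), h[0]))
    used = set()
    keep = []
    for s, e, g in hits:
        if used & set(range(s, e)):
            continue
        used |= set(range(s, e))
        keep.append((s, e, g))
    return sorted(keep)


@st.composite
def _random_case(draw):
    n_terms = draw(st.integers(1, 10))
    terms = set()
    for _ in range(n_terms):
        k = draw(st.integers(1, 2))
        terms.add(" ".join(draw(st.sampled_from(_VOCAB)) for _ in range(k)))
    terms = sorted(terms)
    assignment = {
        t: draw(st.sampled_from(PRIMARY_EMOTIONS)) for t in terms
    }
    tokens = draw(st.lists(st.sampled_from(_VOCAB), max_size=30))
    return assignment, tokens


@settings(max_examples=80, deadline=None)
@given(_random_case())
def test_annotate_equals_bruteforce_oracle(case):
    assignment, tokens = case
    by_primary = {}
    for term, prim in assignment.items():
        by_primary.setdefault(prim, []).append(term)
    term_map = {f"{p}_terms": (p, syns) for p, syns in by_primary.items()}
    lex = _lex(term_map)
    got = sorted((a.span[0], a.span[1], a.matched_term) for a in annotate(_ct(tokens), lex))
    assert got == _oracle(list(tokens), lex)


def test_adding_disjoint_synonym_preserves_existing_annotations(lexicon):
    toks = ["qa", "qb", "happy"]
    lex1 = _lex({"mel": ("sadness", ["qa qb"])})
    base = {(a.span, a.matched_term) for a in annotate(_ct(toks), lex1)}
    lex2 = _lex({"mel": ("sadness", ["qa qb"]), "cheer": ("joy", ["happy"])})
    extended = {(a.span, a.matched_term) for a in annotate(_ct(toks), lex2)}
    assert base <= extended


# ---------------------------------------------------------------------------
# profiles


class TestProfile:
    def test_empty_annotations_give_zero_flags(self):
        p = profile([], "r0")
        assert all(v == 0 for v in p.flags.values())

    def test_counts_and_flags(self, lexicon):
        anns = annotate(_ct(["happy", "glee", "worry"]), lexicon, review_id="r1")
        p = profile(anns, "r1")
        assert p.flags["joy"] == 1 and p.n_matches["joy"] == 2
        assert p.flags["fear"] == 1 and p.n_matches["fear"] == 1
        assert p.flags["anger"] == 0

    def test_flags_invariant_under_term_duplication(self, lexicon):
        p1 = profile(annotate(_ct(["happy"]), lexicon, "r"), "r")
        p2 = profile(annotate(_ct(["happy", "happy", "happy"]), lexicon, "r"), "r")
        assert p1.flags == p2.flags

    def test_mixed_review_ids_rejected(self, lexicon):
        anns = annotate(_ct(["happy"]), lexicon, review_id="a")
        with pytest.raises(ValueError):
            profile(anns, "b")


class TestAnnotateCorpus:
    def _rec(self, i, text):
        return ReviewRecord(review_id=f"r{i}", source="synthetic", drug="sildenafil", text=text)

    def test_empty_corpus(self, lexicon):
        assert annotate_corpus([], lexicon) == ([], [])

    def test_empty_text_records_are_skipped_and_counted(self, lexicon):
        recs = [self._rec(i, "happy tablet morning") for i in range(8)]
        recs.insert(2, self._rec(90, ""))
        recs.insert(5, self._rec(91, "  100 200  "))  # nontextual after cleaning
        profiles, skipped = annotate_corpus(recs, lexicon)
        assert len(profiles) == 8
        assert sorted(skipped) == ["r90", "r91"]

    def test_order_preserved(self, lexicon):
        recs = [self._rec(i, f"happy tablet morning x{i}") for i in range(10)]
        profiles, _ = annotate_corpus(recs, lexicon)
        assert [p.review_id for p in profiles] == [r.review_id for r in recs]
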