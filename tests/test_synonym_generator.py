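import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obosyn.obo_io import SynonymEntry, SynonymScope, parse_obo_text
from obosyn.overlap_finder import LexicalOverlap, find_overlaps
from obosyn.pipeline import prune_model
from obosyn.synonym_generator import (
    SubstitutionError,
    generate_all,
    infer_scope,
    scope_meet,
    substitute,
)
from obosyn.textnorm import normalize_phrase

E, B, N, R, U = (
    SynonymScope.EXACT,
    SynonymScope.BROAD,
    SynonymScope.NARROW,
    SynonymScope.RELATED,
    SynonymScope.UNSPECIFIED,
)


def _overlap(desc_text, overlap_text, anc="A:1", desc="D:1",
             anc_scope=E, desc_scope=E):
    desc_phrase = normalize_phrase(desc_text)
    anc_phrase = normalize_phrase(overlap_text)
    start = None
    for i in range(len(desc_phrase.tokens) - len(anc_phrase.tokens) + 1):
        if desc_phrase.tokens[i : i + len(anc_phrase.tokens)] == anc_phrase.tokens:
            start = i
            break
    assert start is not None
    return LexicalOverlap(
        ancestor_id=anc,
        descendant_id=desc,
        ancestor_synonym=SynonymEntry(overlap_text, anc_scope),
        descendant_synonym=SynonymEntry(desc_text, desc_scope),
        start=start,
        length=len(anc_phrase.tokens),
    )


class TestSubstitute:
    @pytest.mark.parametrize(
        ("descendant", "overlap", "replacement", "expected"),
        [
            # the canonical hearing-loss substitution
            ("sensorineural hearing loss", "hearing loss",
             "hearing defect", "sensorineural hearing defect"),
            # second worked substitution: flanks are preserved verbatim
            ("high-tone sensorineural hearing impairment", "hearing impairment",
             "hearing loss", "high tone sensorineural hearing loss"),
            # five published example rows
            ("Cortical cataract", "Cataract", "Lens opacities",
             "Cortical lens opacities"),
            ("Neoplasm of the skin", "Neoplasm", "Cancer", "Cancer of the skin"),
            ("Profound hearing impairment", "Hearing impairment", "Hearing loss",
             "Profound hearing loss"),
            ("Atypical absence seizures", "Seizures", "Epilepsy",
             "Atypical absence epilepsy"),
            ("Unilateral renal aplasia", "Renal aplasia", "Renal agenesis",
             "Unilateral renal agenesis"),
        ],
    )
    def test_worked_substitutions(self, descendant, overlap, replacement, expected):
        cand = substitute(_overlap(descendant, overlap), SynonymEntry(replacement, E))
        assert cand.text == expected

    def test_replacement_equal_to_overlap_rejected(self):
        with pytest.raises(SubstitutionError):
            substitute(
                _overlap("sensorineural hearing loss", "hearing loss"),
                SynonymEntry("Hearing loss", E),
            )

    def test_substitution_at_recorded_position_only(self):
        o = _overlap("ab cd ab", "ab")
        o2 = LexicalOverlap(**{**o.__dict__, "start": 2})
        c1 = substitute(o, SynonymEntry("xy", E))
        c2 = substitute(o2, SynonymEntry("xy", E))
        assert (c1.text, c2.text) == ("xy cd ab", "ab cd xy")

    @given(
        st.lists(st.sampled_from("abcdef"), min_size=1, max_size=4),
        st.lists(st.sampled_from("ghij"), min_size=1, max_size=3),
        st.lists(st.sampled_from("klmn"), min_size=1, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_token_arithmetic_and_reversibility(self, flank, overlap, repl):
        """len(candidate) = len(descendant) - len(overlap) + len(replacement);
        substituting the overlap back recovers the descendant."""
        desc_tokens = flank + overlap
        desc = " ".join(desc_tokens)
        ov = " ".join(overlap)
        rep = " ".join(repl)
        if rep == ov:
            return
        o = _overlap(desc, ov)
        cand = substitute(o, SynonymEntry(rep, E))
        ct = normalize_phrase(cand.text).tokens
        assert len(ct) == len(desc_tokens) - len(overlap) + len(repl)
        back = LexicalOverlap(
            ancestor_id=o.ancestor_id,
            descendant_id=o.descendant_id,
            ancestor_synonym=SynonymEntry(rep, E),
            descendant_synonym=SynonymEntry(cand.text, cand.scope),
            start=o.start,
            length=len(repl),
        )
        restored = substitute(back, SynonymEntry(ov, E))
        assert normalize_phrase(restored.text).normalized == \
            normalize_phrase(desc).normalized


class TestScopeInference:
    @pytest.mark.parametrize(
        ("scopes", "expected"),
        [
            ((E, E, R), R),  # related replacement propagates
            ((E, E, E), E),
            ((E, U, E), U),  # no relatedness information wins
            ((E, N, E), N),
            ((N, B, E), R),  # narrow vs broad are incomparable
            ((R, N, B), R),
            ((U, R, N), U),
        ],
    )
    def test_most_restrictive_scope(self, scopes, expected):
        assert infer_scope(*scopes) is expected

    @given(st.sampled_from([E, B, N, R, U]), st.sampled_from([E, B, N, R, U]),
           st.sampled_from([E, B, N, R, U]))
    @settings(max_examples=125, deadline=None)
    def test_meet_commutative_associative(self, a, b, c):
        assert scope_meet(a, b) is scope_meet(b, a)
        assert scope_meet(scope_meet(a, b), c) is scope_meet(a, scope_meet(b, c))
        assert scope_meet(a, E) is a  # EXACT is the identity

    def test_inferred_scope_flows_into_candidate(self):
        """A RELATED replacement yields a RELATED generated synonym, as in
        the respiratory-infection example."""
        o = _overlap(
            "Acute respiratory tract infection", "Respiratory tract infection"
        )
        cand = substitute(o, SynonymEntry("Respiratory infections", R))
        assert cand.text == "Acute respiratory infections"
        assert cand.scope is R


OBO_SMALL = """\
[Term]
id: X:1
name: Alpha root

[Term]
id: X:2
name: Hearing impairment
synonym: "Hearing loss" EXACT []
synonym: "Hearing defect" EXACT []
synonym: "Hypoacusis" EXACT []
is_a: X:1

[Term]
id: X:3
name: Sensorineural hearing impairment
synonym: "Sensorineural hearing loss" EXACT []
is_a: X:2
"""


class TestGenerateAll:
    def test_one_overlap_times_replacements(self):
        model = parse_obo_text(OBO_SMALL)
        overlaps = [o for o in find_overlaps(model)
                    if o.descendant_synonym.text == "Sensorineural hearing loss"]
        assert len(overlaps) == 1  # only "hearing loss" fits inside it
        res = generate_all(model, overlaps, max_depth=1)
        # replacements: name + 3 synonyms of X:2, minus the overlapped one
        assert res.n_candidates == 3
        texts = {c.text for c in res.candidates}
        assert texts == {
            "Sensorineural hearing impairment",
            "Sensorineural hearing defect",
            "Sensorineural hypoacusis",
        }

    def test_existing_vs_novel_partition(self):
        model = parse_obo_text(OBO_SMALL)
        res = generate_all(model, find_overlaps(model))
        assert res.n_candidates == len(res.existing) + len(res.novel)
        known = model.synonym_strings()
        assert all(c.normalized in known for c in res.existing)
        assert all(c.normalized not in known for c in res.novel)
        # "Sensorineural hearing impairment" regenerates the existing name
        assert any(
            c.text == "Sensorineural hearing impairment" for c in res.existing
        )

    def test_zero_overlaps_empty_result(self):
        model = parse_obo_text(OBO_SMALL)
        res = generate_all(model, [])
        assert res.n_candidates == 0 and res.novel == []

    def test_bad_depth_rejected(self):
        model = parse_obo_text(OBO_SMALL)
        with pytest.raises(ValueError, match="max_depth"):
            generate_all(model, [], max_depth=0)

    def test_depth_monotonicity(self):
        model = parse_obo_text(OBO_SMALL)
        overlaps = find_overlaps(model)
        d1 = {(c.term_id, c.normalized)
              for c in generate_all(model, overlaps, max_depth=1).candidates}
        d2 = {(c.term_id, c.normalized)
              for c in generate_all(model, overlaps, max_depth=2).candidates}
        assert d1 <= d2

    def test_novel_attachable_never_clashes_with_ontology(self):
        from obosyn.fixtures import FixtureSpec, synth_ontology

        fx = synth_ontology(FixtureSpec(seed=13, n_roots=2, depth=4, branching=2))
        pruned, _ = prune_model(fx.model)
        res = generate_all(
            pruned, find_overlaps(pruned), known_strings=fx.model.synonym_strings()
        )
        known = fx.model.synonym_strings()
        for c in res.attachable(pruned):
            assert c.normalized not in known
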