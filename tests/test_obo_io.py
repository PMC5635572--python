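import textwrap

import obonet
import pytest

from obosyn.fixtures import FixtureSpec, synth_ontology
from obosyn.obo_io import (
    OboParseError,
    OntologyValidationError,
    SynonymEntry,
    SynonymScope,
    parse_obo,
    parse_obo_text,
    read_candidates,
    write_candidates,
    write_enriched_obo,
    write_obo,
)
from obosyn.synonym_generator import CandidateSynonym


def dedent(s):
    return textwrap.dedent(s)


class TestParsing:
    def test_hearing_fixture_structure(self, hearing_model):
        t = hearing_model.terms["HP:0000407"]
        assert t.name == "Sensorineural hearing impairment"
        assert t.parents == ("HP:0000365",)
        assert [s.text for s in t.synonyms] == ["Sensorineural hearing loss"]
        assert t.synonyms[0].scope is SynonymScope.EXACT

    def test_name_registered_as_exact_synonym(self, hearing_model):
        entries = hearing_model.terms["HP:0000365"].synonym_entries()
        assert entries[0] == SynonymEntry(
            "Hearing impairment", SynonymScope.EXACT
        )
        assert len(entries) == 4  # name + 3 synonyms

    def test_empty_file_gives_empty_model(self):
        model = parse_obo_text("format-version: 1.2\n")
        assert model.terms == {}

    def test_scopeless_synonym_is_unspecified(self):
        text = dedent(
            """\
            [Term]
            id: X:1
            name: Alpha
            synonym: "alpha variant" []
            """
        )
        model = parse_obo_text(text)
        assert model.terms["X:1"].synonyms[0].scope is SynonymScope.UNSPECIFIED

    def test_obsolete_flag_and_unknown_tags_ignored(self):
        text = dedent(
            """\
            [Term]
            id: X:1
            name: Alpha
            def: "irrelevant" [PMID:1]
            xref: UMLS:C000
            is_obsolete: true
            """
        )
        model = parse_obo_text(text)
        assert model.terms["X:1"].obsolete
        assert model.non_obsolete() == []

    def test_is_a_trailing_comment_stripped(self):
        text = dedent(
            """\
            [Term]
            id: X:1
            name: Alpha

            [Term]
            id: X:2
            name: Beta
            is_a: X:1 ! Alpha
            """
        )
        assert parse_obo_text(text).terms["X:2"].parents == ("X:1",)

    def test_typedef_stanzas_skipped(self):
        text = dedent(
            """\
            [Typedef]
            id: part_of
            name: part of

            [Term]
            id: X:1
            name: Alpha
            """
        )
        assert list(parse_obo_text(text).terms) == ["X:1"]

    @pytest.mark.parametrize(
        ("snippet", "message_part"),
        [
            ("[Term]\nid: X:1\nname: A\nno colon here\n", "line 4"),
            ("[Term]\nid: X:1\nname: A\n\n[Term]\nid: X:1\nname: B\n", "duplicate"),
            ("[Term]\nname: A\n", "no id"),
            ("[Term]\nid: X:1\nname: A\nsynonym: unquoted EXACT\n", "synonym"),
        ],
    )
    def test_parse_errors_name_the_problem(self, snippet, message_part):
        with pytest.raises(OboParseError, match=message_part):
            parse_obo_text(snippet)

    def test_dangling_is_a_listed(self):
        text = "[Term]\nid: X:1\nname: A\nis_a: X:999\n"
        with pytest.raises(OntologyValidationError, match="X:999"):
            parse_obo_text(text)

    def test_cycle_named(self):
        text = dedent(
            """\
            [Term]
            id: X:1
            name: A
            is_a: X:2

            [Term]
            id: X:2
            name: B
            is_a: X:1
            """
        )
        with pytest.raises(OntologyValidationError, match="cycle"):
            parse_obo_text(text)


class TestRoundTrip:
    def test_fixture_round_trips_exactly(self, tmp_path):
        fx = synth_ontology(FixtureSpec(seed=11, n_roots=2, depth=3, branching=2))
        path = tmp_path / "fx.obo"
        write_obo(fx.model, path)
        back = parse_obo(path)
        assert back.terms == fx.model.terms

    def test_synthetic_fixture_matches_declared_counts(self):
        fx = synth_ontology(FixtureSpec(seed=5, n_roots=2, depth=3, branching=2))
        model = parse_obo_text(fx.obo_text)
        assert len(model.terms) == len(fx.model.terms)
        edges = {(p, t.id) for t in model for p in t.parents}
        assert edges == set(fx.edges)
        n_syn = sum(
            len(t.synonym_entries(include_name=True))
            for t in model.non_obsolete()
        )
        assert n_syn == fx.synonyms_including_names

    def test_synonym_quotes_escaped(self, tmp_path):
        from obosyn.obo_io import OntologyModel, Term

        model = OntologyModel(
            terms={
                "X:1": Term(
                    id="X:1",
                    name="Alpha",
                    synonyms=(SynonymEntry('say "hi" now', SynonymScope.EXACT),),
                )
            }
        )
        path = tmp_path / "q.obo"
        write_obo(model, path)
        assert parse_obo(path).terms == model.terms

    def test_cross_check_against_obonet(self, tmp_path, hearing_model):
        """Independent OBO reader agrees on ids, names and is_a edges."""
        path = tmp_path / "hearing.obo"
        write_obo(hearing_model, path)
        graph = obonet.read_obo(path)
        assert set(graph.nodes) == set(hearing_model.terms)
        for node, data in graph.nodes(data=True):
            assert data["name"] == hearing_model.terms[node].name
        ours = {
            (t.id, p) for t in hearing_model for p in t.parents
        }
        theirs = {
            (u, v)
            for u, v, k in graph.edges(keys=True)
            if k == "is_a"
        }
        assert ours == theirs


def _candidate(term_id, text, term_name="T", validated=None):
    return CandidateSynonym(
        term_id=term_id,
        term_name=term_name,
        text=text,
        scope=SynonymScope.RELATED,
        ancestor_id="HP:0000365",
        replacement_text="hearing loss",
        overlap_text="hearing impairment",
        descendant_text=text,
        corpus_validated=validated,
    )


class TestCandidateReport:
    def test_single_candidate_row(self, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates(
            [_candidate("HP:0012715", "Profound hearing loss",
                        term_name="Profound hearing impairment", validated=True)],
            path,
        )
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t")[0] == "term_id"
        row = lines[1].split("\t")
        assert row[:3] == ["HP:0012715", "Profound hearing impairment",
                           "Profound hearing loss"]
        assert row[-1] == "true"

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates([], path)
        assert len(path.read_text().splitlines()) == 1

    def test_rows_sorted_by_term_then_text(self, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates(
            [
                _candidate("X:2", "beta"),
                _candidate("X:1", "zeta"),
                _candidate("X:1", "alpha"),
            ],
            path,
        )
        rows = [ln.split("\t")[:3] for ln in path.read_text().splitlines()[1:]]
        assert [(r[0], r[2]) for r in rows] == [
            ("X:1", "alpha"),
            ("X:1", "zeta"),
            ("X:2", "beta"),
        ]

    def test_round_trip_through_read_candidates(self, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates([_candidate("X:1", "alpha beta", validated=False)], path)
        back = read_candidates(path)
        assert len(back) == 1
        assert back[0].text == "alpha beta"
        assert back[0].corpus_validated is False


class TestEnrichedObo:
    def test_round_trip_adds_exactly_accepted(self, tmp_path, hearing_model):
        cand = _candidate(
            "HP:0000407", "Sensorineural hearing defect",
            term_name="Sensorineural hearing impairment",
        )
        path = tmp_path / "enriched.obo"
        write_enriched_obo(hearing_model, [cand], path)
        back = parse_obo(path)
        extra = set(back.terms["HP:0000407"].synonyms) - set(
            hearing_model.terms["HP:0000407"].synonyms
        )
        assert {e.text for e in extra} == {"Sensorineural hearing defect"}
        for tid in hearing_model.terms:
            if tid != "HP:0000407":
                assert back.terms[tid] == hearing_model.terms[tid]

    def test_zero_candidates_is_identity_rewrite(self, tmp_path, hearing_model):
        a, b = tmp_path / "a.obo", tmp_path / "b.obo"
        write_obo(hearing_model, a)
        write_enriched_obo(hearing_model, [], b)
        assert a.read_bytes() == b.read_bytes()

    def test_unknown_term_rejected(self, tmp_path, hearing_model):
        with pytest.raises(OntologyValidationError, match="unknown term"):
            write_enriched_obo(
                hearing_model, [_candidate("HP:9999999", "x y")], tmp_path / "x.obo"
            )

    def test_duplicate_synonym_rejected_case_insensitively(
        self, tmp_path, hearing_model
    ):
        with pytest.raises(OntologyValidationError, match="duplicates"):
            write_enriched_obo(
                hearing_model,
                [_candidate("HP:0000365", "HEARING LOSS")],
                tmp_path / "x.obo",
            )
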