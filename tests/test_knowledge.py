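"""Lexicon, schema, normalization and dictionary lookup."""

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from medrelex.knowledge import (
    Category,
    KnowledgeError,
    Lexicon,
    Concept,
    UnknownTypeError,
    allowed_relations,
    category_of,
    load_lexicon,
    load_schema,
    load_seed_pairs,
    lookup,
    normalize_term,
    save_lexicon,
    term_key,
)


def _write_yaml(path, data):
    path.write_text(yaml.safe_dump(data), encoding="utf-8")


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Swine  Influenza ", "swine influenza"),
        ("", ""),
        ("AMOX", "amox"),
        ("  a\tb\nc ", "a b c"),
    ],
)
def test_normalize_term(raw, expected):
    assert normalize_term(raw) == expected


@given(st.text(max_size=40))
def test_normalize_term_is_idempotent(s):
    once = normalize_term(s)
    assert normalize_term(once) == once


class TestLoadLexicon:
    def test_resolves_terms_to_concepts(self, tmp_path, schema):
        path = tmp_path / "lex.yaml"
        _write_yaml(
            path,
            {
                "concepts": [
                    {
                        "id": "C0012798",
                        "preferred_name": "Diazoxide",
                        "semantic_types": ["Pharmacologic Substance"],
                    }
                ]
            },
        )
        lex = load_lexicon(path, schema)
        assert lex.term_index["diazoxide"] == ["C0012798"]

    def test_empty_sections_give_empty_lexicon(self, tmp_path, schema):
        path = tmp_path / "lex.yaml"
        _write_yaml(path, {"concepts": []})
        lex = load_lexicon(path, schema)
        assert lex.term_index == {} and lex.concepts == {}

    def test_unknown_semantic_type_is_rejected_by_name(self, tmp_path, schema):
        path = tmp_path / "lex.yaml"
        _write_yaml(
            path,
            {
                "concepts": [
                    {"id": "X1", "preferred_name": "thing", "semantic_types": ["Bogus Type"]}
                ]
            },
        )
        with pytest.raises(UnknownTypeError, match="Bogus Type"):
            load_lexicon(path, schema)

    def test_missing_file(self, schema, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_lexicon(tmp_path / "nope.yaml", schema)

    def test_malformed_entry_reports_position(self, tmp_path, schema):
        path = tmp_path / "lex.yaml"
        _write_yaml(path, {"concepts": [{"preferred_name": "no id here"}]})
        with pytest.raises(KnowledgeError, match=r"concepts\[0\]"):
            load_lexicon(path, schema)

    def test_round_trip_preserves_term_index(self, tmp_path, lexicon, schema):
        out = tmp_path / "roundtrip.yaml"
        save_lexicon(lexicon, out)
        again = load_lexicon(out, schema)
        assert again.term_index == lexicon.term_index
        assert again.stoplist == lexicon.stoplist


class TestLookup:
    def _mini(self, terms):
        concepts = [
            Concept(id=f"C{i}", preferred_name=t, semantic_types=("Disease or Syndrome",))
            for i, t in enumerate(terms)
        ]
        lex = Lexicon(concepts=concepts)
        for c in concepts:
            lex.add_term(c.preferred_name, c.id)
        return lex

    def test_multiword_term_inside_longer_phrase(self, lexicon):
        matches = lookup(lexicon, "major cardiovascular disease outcomes")
        assert len(matches) == 1
        (m,) = matches
        assert m.key == "cardiovascular disease outcomes"
        assert (m.token_start, m.token_end) == (1, 4)

    def test_repeated_term_matches_twice_without_overlap(self):
        lex = self._mini(["aspirin"])
        matches = lookup(lex, "aspirin aspirin")
        assert [(m.token_start, m.token_end) for m in matches] == [(0, 1), (1, 2)]

    def test_longest_match_wins_over_nested_term(self):
        lex = self._mini(["disease", "heart disease"])
        matches = lookup(lex, "chronic heart disease")
        assert len(matches) == 1
        assert matches[0].key == "heart disease"

    def test_agrees_with_bruteforce_tiling_oracle(self):
        from _oracles import greedy_longest_tiling

        terms = ["disease", "heart disease", "heart", "valve disease", "aspirin"]
        lex = self._mini(terms)
        phrases = [
            "heart disease",
            "heart valve disease",
            "disease of heart",
            "aspirin for heart disease",
            "no match here",
            "heart heart disease disease",
        ]
        for phrase in phrases:
            words = phrase.split()
            expected = greedy_longest_tiling({t for t in terms}, words)
            got = [(m.token_start, m.token_end) for m in lookup(lex, phrase)]
            assert got == expected, phrase

    def test_unknown_phrase_is_empty(self, lexicon):
        assert lookup(lexicon, "entirely unrelated words") == []

    def test_matches_never_overlap_and_stay_inside_phrase(self, lexicon):
        phrase = "fosfomycin and amoxicillin-clavulanate for cystitis and swine flu"
        matches = lookup(lexicon, phrase)
        assert len(matches) == 4
        for a, b in zip(matches, matches[1:]):
            assert a.end <= b.start
        assert matches[0].start >= 0 and matches[-1].end <= len(phrase)


class TestSchema:
    @pytest.mark.parametrize(
        "type_name,category",
        [
            ("Disease or Syndrome", Category.PROBLEM),
            ("Pharmacologic Substance", Category.TREATMENT),
            ("Diagnostic Procedure", Category.TEST),
        ],
    )
    def test_category_of(self, schema, type_name, category):
        assert category_of(schema, type_name) is category

    def test_category_of_unknown_type(self, schema):
        with pytest.raises(UnknownTypeError):
            category_of(schema, "No Such Type")

    def test_procedure_disease_pair_licenses_treats_prevents_complicates(self, schema):
        rels = allowed_relations(
            schema, "Therapeutic or Preventive Procedure", "Disease or Syndrome"
        )
        assert {"treats", "prevents", "complicates"} <= set(rels)
        ranks = [schema.relation_ranks[r] for r in rels]
        assert ranks == sorted(ranks)

    def test_unlicensed_pair_is_empty(self, schema):
        assert allowed_relations(schema, "Disease or Syndrome", "Pharmacologic Substance") == []

    def test_every_licensed_list_is_rank_sorted_and_duplicate_free(self, schema):
        for (src, tgt) in schema.licensed:
            rels = allowed_relations(schema, src, tgt)
            assert len(set(rels)) == len(rels)
            assert sorted(rels, key=schema.relation_ranks.__getitem__) == rels

    def test_bad_rank_permutation_rejected(self, tmp_path):
        path = tmp_path / "schema.yaml"
        _write_yaml(
            path,
            {
                "types": [{"name": "T", "category": "Problem"}],
                "relations": [
                    {"name": n, "rank": 1}
                    for n in (
                        "treats prevents causes complicates diagnoses sign_or_symptom_of".split()
                    )
                ],
            },
        )
        with pytest.raises(KnowledgeError, match="permutation"):
            load_schema(path)


class TestSeedPairs:
    def test_load_and_validate(self, tmp_path, lexicon):
        path = tmp_path / "seeds.tsv"
        path.write_text("C0012798\ttreats\tC0020615\n", encoding="utf-8")
        (seed,) = load_seed_pairs(path, lexicon)
        assert (seed.concept1_id, seed.relation, seed.concept2_id) == (
            "C0012798",
            "treats",
            "C0020615",
        )

    def test_unknown_concept_reports_line(self, tmp_path, lexicon):
        path = tmp_path / "seeds.tsv"
        path.write_text("# comment\nC0012798\ttreats\tCXXXXXX\n", encoding="utf-8")
        with pytest.raises(KnowledgeError, match="line 2"):
            load_seed_pairs(path, lexicon)


def test_term_key_ignores_punctuation_spacing():
    assert term_key("Rhinitis, Vasomotor") == term_key("rhinitis ,  vasomotor")
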