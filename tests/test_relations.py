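"""Pattern dialect, specialization degree, matching and extraction."""

import random

import pytest

from _oracles import oracle_match

from medrelex.knowledge import allowed_relations
from medrelex.ner import EntityMention, recognize
from medrelex.relations import (
    CompiledPattern,
    ExtractionConfig,
    PatternError,
    PatternSpec,
    compile_pattern,
    compile_patterns,
    extract,
    match,
    specialization_degree,
    triple_from_dict,
    triple_to_dict,
)
from medrelex.segmentation import Token, tokenize


def compile_simple(template, relation="treats", pattern_id="p"):
    return compile_pattern(PatternSpec(pattern_id=pattern_id, relation=relation, template=template))


def sentence_with_mentions(words, e1_word="drugx", e2_word="disy",
                           e1_cat="Treatment", e2_cat="Problem"):
    """Build tokens plus single-token E1/E2 mentions from a word list."""
    text = " ".join(words)
    tokens = tokenize(text)
    mentions = {}
    for tok in tokens:
        if tok.text == e1_word and 1 not in mentions:
            mentions[1] = EntityMention(
                doc_id="d", start=tok.start, end=tok.end, surface=tok.text,
                concept_id="CE1", semantic_type="T1", category=e1_cat,
            )
        elif tok.text == e2_word and 2 not in mentions:
            mentions[2] = EntityMention(
                doc_id="d", start=tok.start, end=tok.end, surface=tok.text,
                concept_id="CE2", semantic_type="T2", category=e2_cat,
            )
    return tokens, mentions.get(1), mentions.get(2)


class TestSpecializationDegree:
    @pytest.mark.parametrize(
        "template,expected",
        [
            ("E1 may trigger E2", 2),
            ("E1 ... E2", 0),
            ("E1 for prophylaxis against E2", 3),
            ("E1 is the best test for (the diagnoses of)? E2", 5),
            ("E1 (appears|was found) to help E2", 3),  # min over branches + 2
            ("E1 ... effective (for|against) E2", 2),
        ],
    )
    def test_counts_obligatory_literals(self, template, expected):
        assert specialization_degree(template) == expected

    def test_declared_degree_overrides_computed(self):
        p = compile_pattern(
            PatternSpec(pattern_id="p", relation="treats",
                        template="E1 may trigger E2", declared_degree=9)
        )
        assert p.degree == 9


class TestCompileErrors:
    @pytest.mark.parametrize(
        "template",
        [
            "E1 E1 treats E2",  # duplicate E1
            "E1 treats treats",  # missing E2
            "E1 (and E2)? maybe",  # slot inside a group
            "E1 (unclosed E2",
        ],
    )
    def test_invalid_templates_rejected(self, template):
        with pytest.raises(PatternError):
            compile_simple(template)

    def test_unknown_category_named(self):
        with pytest.raises(PatternError, match="Bogus"):
            compile_simple("E1[Bogus] treats E2")

    def test_unknown_relation(self):
        with pytest.raises(PatternError):
            compile_pattern(PatternSpec(pattern_id="p", relation="cures", template="E1 x E2"))


class TestMatch:
    def test_diazoxide_reduce_pattern(self):
        pat = compile_simple("E1 was found to reduce E2")
        toks, e1, e2 = sentence_with_mentions(
            "drugx was found to reduce disy .".split()
        )
        assert match(pat, toks, e1, e2)

    def test_swapped_text_order_fails(self):
        pat = compile_simple("E1 was found to reduce E2")
        toks, e1, e2 = sentence_with_mentions(
            "disy was found to reduce drugx .".split()
        )
        assert not match(pat, toks, e1, e2)

    def test_category_mismatch_fails_before_textual_match(self):
        pat = compile_simple("E1 was found to reduce E2")
        toks, e1, e2 = sentence_with_mentions(
            "drugx was found to reduce disy".split(), e1_cat="Problem"
        )
        assert not match(pat, toks, e1, e2)

    def test_optional_group_both_ways(self):
        pat = compile_simple("E1 is the best test for (the diagnoses of)? E2",
                             relation="diagnoses")
        toks, e1, e2 = sentence_with_mentions(
            "drugx is the best test for disy".split(), e1_cat="Test"
        )
        assert match(pat, toks, e1, e2)
        toks2, e1b, e2b = sentence_with_mentions(
            "drugx is the best test for the diagnoses of disy".split(), e1_cat="Test"
        )
        assert match(pat, toks2, e1b, e2b)

    def test_gap_respects_token_bound(self):
        pat = compile_simple("E1 ... helps E2")
        filler = ["w%d" % i for i in range(7)]
        toks, e1, e2 = sentence_with_mentions(["drugx"] + filler[:6] + ["helps", "disy"])
        assert match(pat, toks, e1, e2)
        toks2, e1b, e2b = sentence_with_mentions(["drugx"] + filler + ["helps", "disy"])
        assert not match(pat, toks2, e1b, e2b)

    def test_literal_never_matches_token_substring(self):
        pat = compile_simple("E1 is E2")
        toks, e1, e2 = sentence_with_mentions("drugx isolates disy".split())
        assert not match(pat, toks, e1, e2)

    def test_coordination_group_fills_the_slot(self):
        pat = compile_simple("E1 helps E2")
        text = "drugx and otherdrug helps disy"
        tokens = tokenize(text)
        def mk(word, cat, stype, cid):
            tok = next(t for t in tokens if t.text == word)
            return EntityMention(doc_id="d", start=tok.start, end=tok.end,
                                 surface=word, concept_id=cid,
                                 semantic_type=stype, category=cat)
        e1 = mk("drugx", "Treatment", "T1", "C1")
        e1b = mk("otherdrug", "Treatment", "T1", "C2")
        e2 = mk("disy", "Problem", "T2", "C3")
        # each coordinated treatment can fill E1
        assert match(pat, tokens, e1, e2, mentions=[e1, e1b, e2])
        assert match(pat, tokens, e1b, e2, mentions=[e1, e1b, e2])
        # without knowledge of the sibling mention, the first cannot reach "helps"
        assert not match(pat, tokens, e1, e2, mentions=[e1, e2])


class TestMatchOracleEquivalence:
    """Compiled-regex matching equals exhaustive template expansion."""

    VOCAB = ["alpha", "beta", "gamma", "delta"]
    NOISE = ["n1", "n2", "n3", "alpha", "beta"]

    def random_template(self, rng):
        units = []
        for _ in range(rng.randint(1, 4)):
            kind = rng.choice(["lit", "gap", "opt", "alt"])
            if kind == "lit":
                units.append(rng.choice(self.VOCAB))
            elif kind == "gap":
                units.append("...")
            elif kind == "opt":
                units.append(
                    "(" + " ".join(rng.sample(self.VOCAB, rng.randint(1, 2))) + ")?"
                )
            else:
                units.append(
                    "(" + rng.choice(self.VOCAB) + "|" + rng.choice(self.VOCAB) + ")"
                )
        slots = ["E1", "E2"] if rng.random() < 0.8 else ["E2", "E1"]
        pos1 = rng.randint(0, len(units))
        units.insert(pos1, slots[0])
        pos2 = rng.randint(pos1 + 1, len(units))
        units.insert(pos2, slots[1])
        return " ".join(units)

    def random_sentence(self, rng):
        words = [rng.choice(self.NOISE) for _ in range(rng.randint(2, 9))]
        i = rng.randint(0, len(words))
        words.insert(i, "drugx")
        j = rng.randint(0, len(words))
        while j == i:
            j = rng.randint(0, len(words))
        words.insert(j, "disy")
        return words

    def test_200_random_instances(self):
        rng = random.Random(987654)
        n_true = 0
        for _ in range(200):
            template = self.random_template(rng)
            words = self.random_sentence(rng)
            pat = compile_simple(template)
            toks, e1, e2 = sentence_with_mentions(words)
            got = match(pat, toks, e1, e2, mentions=[e1, e2])
            elements = [
                "E1" if w == "drugx" else "E2" if w == "disy" else w for w in words
            ]
            want = oracle_match(template, elements)
            assert got == want, (template, words)
            n_true += got
        assert 0 < n_true < 200  # both outcomes exercised


class TestExtract:
    def test_coordinated_treatments_give_two_triples(self, lexicon, schema, patterns):
        sent = (
            "Fosfomycin and amoxicillin-clavulanate appear to be effective "
            "for cystitis caused by susceptible isolates"
        )
        mentions = recognize(sent, lexicon, schema, doc_id="d")
        triples = extract(sent, mentions, patterns, schema)
        got = sorted((t.source.surface, t.relation, t.target.surface) for t in triples)
        assert got == [
            ("Fosfomycin", "treats", "cystitis"),
            ("amoxicillin-clavulanate", "treats", "cystitis"),
        ]

    def test_no_pattern_match_no_triples(self, lexicon, schema, patterns):
        sent = "aspirin and migraine were discussed at length"
        mentions = recognize(sent, lexicon, schema)
        assert extract(sent, mentions, patterns, schema) == []

    def test_relation_order_decides_between_competing_relations(self, schema):
        # the pair matches both a treats and a prevents pattern; the
        # relation earlier in rank order (treats) must win
        pats = compile_patterns(
            [
                PatternSpec(pattern_id="t1", relation="treats", template="E1 alpha beta E2"),
                PatternSpec(pattern_id="p1", relation="prevents", template="E1 alpha ... E2"),
            ]
        )
        words = "aspirin alpha beta migraine".split()
        toks = tokenize(" ".join(words))
        e1 = EntityMention(doc_id="d", start=toks[0].start, end=toks[0].end,
                           surface="aspirin", concept_id="C1",
                           semantic_type="Pharmacologic Substance", category="Treatment")
        e2 = EntityMention(doc_id="d", start=toks[3].start, end=toks[3].end,
                           surface="migraine", concept_id="C2",
                           semantic_type="Disease or Syndrome", category="Problem")
        triples = extract(" ".join(words), [e1, e2], pats, schema)
        # independent oracle: enumerate all (relation, pattern) matches and
        # apply the ordering rule by hand
        matches = {
            p.relation
            for p in pats
            if match(p, toks, e1, e2, mentions=[e1, e2])
        }
        assert matches == {"treats", "prevents"}
        first = min(matches, key=schema.relation_ranks.__getitem__)
        assert [t.relation for t in triples] == [first] == ["treats"]
        # without the one-relation rule both licensed matches surface
        both = extract(" ".join(words), [e1, e2], pats, schema,
                       ExtractionConfig(one_relation_per_pair=False))
        assert {t.relation for t in both} == {"treats", "prevents"}

    def test_degree_orders_patterns_within_a_relation(self, schema):
        pats = compile_patterns(
            [
                PatternSpec(pattern_id="generic", relation="treats", template="E1 alpha ... E2"),
                PatternSpec(pattern_id="specific", relation="treats", template="E1 alpha beta E2"),
            ]
        )
        toks, e1, e2 = sentence_with_mentions("drugx alpha beta disy".split())
        e1 = EntityMention(doc_id="d", start=e1.start, end=e1.end, surface=e1.surface,
                           concept_id="C1", semantic_type="Pharmacologic Substance",
                           category="Treatment")
        e2 = EntityMention(doc_id="d", start=e2.start, end=e2.end, surface=e2.surface,
                           concept_id="C2", semantic_type="Disease or Syndrome",
                           category="Problem")
        triples = extract("drugx alpha beta disy", [e1, e2], pats, schema)
        assert [t.pattern_id for t in triples] == ["specific"]

    def test_output_independent_of_pattern_file_order(self, lexicon, schema, patterns):
        sent = (
            "Fosfomycin and amoxicillin-clavulanate appear to be effective "
            "for cystitis caused by susceptible isolates"
        )
        mentions = recognize(sent, lexicon, schema, doc_id="d")
        shuffled = list(patterns)
        random.Random(3).shuffle(shuffled)
        assert extract(sent, mentions, patterns, schema) == extract(
            sent, mentions, shuffled, schema
        )

    def test_every_triple_is_schema_licensed(self, lexicon, schema, patterns):
        sent = "vaccination prevents influenza and chemotherapy relieves nausea"
        mentions = recognize(sent, lexicon, schema)
        for t in extract(sent, mentions, patterns, schema):
            assert t.relation in allowed_relations(
                schema, t.source.semantic_type, t.target.semantic_type
            )
            assert (t.source.start, t.source.end) != (t.target.start, t.target.end)

    def test_pattern_set_monotonicity_in_all_relations_mode(self, lexicon, schema, patterns):
        """With independent per-relation decisions, removing patterns only
        removes triples and adding patterns only adds them."""
        sent = (
            "Fosfomycin and amoxicillin-clavulanate appear to be effective "
            "for cystitis caused by susceptible isolates"
        )
        cfg = ExtractionConfig(one_relation_per_pair=False)
        mentions = recognize(sent, lexicon, schema, doc_id="d")

        def key_set(pats):
            return {
                (t.source.concept_id, t.relation, t.target.concept_id)
                for t in extract(sent, mentions, pats, schema, cfg)
            }

        full = key_set(patterns)
        for drop in range(len(patterns)):
            reduced = key_set(patterns[:drop] + patterns[drop + 1 :])
            assert reduced <= full


def test_triple_json_round_trip():
    from test_ner import make_mention

    t_src = make_mention(0, 7, "aspirin", stype="Pharmacologic Substance",
                         category="Treatment", concept_id="C1")
    t_tgt = make_mention(15, 23, "migraine", concept_id="C2")
    from medrelex.relations import RelationTriple

    t = RelationTriple(source=t_src, relation="treats", target=t_tgt, pattern_id="x")
    assert triple_from_dict(triple_to_dict(t)) == t
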