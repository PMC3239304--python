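# medrelex

Rule-based extraction of medical entities and the semantic relations
between them, for building high-precision question-answering and semantic
search back-ends over biomedical text.

Clinicians asking "what treats vasomotor rhinitis?" need `<source,
relation, target>` assertions, not ranked documents. `medrelex`
annotates free text in two steps:

1. **Medical entity recognition.** Text is split into sentences
   (abbreviation-aware) and base noun phrases; chunk substrings are mapped
   to concepts in a pluggable lexicon by greedy longest-match dictionary
   lookup; candidates are filtered through a stoplist of noisy general
   words (*best*, *normal*, *take*, *reduce*) and a restriction to
   semantic types that can participate in the targeted relations, then
   disambiguated to one mention per span. Each mention carries a concept
   id, a semantic type (e.g. *Disease or Syndrome*) and a coarse category
   (Problem / Treatment / Test).
2. **Relation extraction.** For every ordered mention pair (E1, E2) the
   semantic schema licenses an ordered list of candidate relations among
   *treats, prevents, causes, complicates, diagnoses, sign_or_symptom_of*.
   Candidates are tried in relation-rank order; within a relation,
   linguistic patterns such as `E1 was found to reduce E2` or
   `E1 is the best test for (the diagnoses of)? E2` are tried most
   specialized first (specialization degree = number of obligatory literal
   tokens). The first successful match emits the triple. Coordinated
   noun phrases are handled, so one sentence can yield several triples.

Annotations are serialized as RDF (Turtle / N-Triples) with span-level
provenance and can be queried with (source, relation, target) forms,
where each field is a category, a term, a concept id or a wildcard.

The package also ships the surrounding workflow: a semi-automatic
pattern-construction pipeline (seed concept pairs → MeSH-qualifier-style
query strings → NXML field extraction → seed-sentence selection →
candidate pattern skeletons for curation), boundary-weighted evaluation
metrics, and a synthetic-corpus module that generates gold-annotated
fixtures and error-injected predictions.

## Evaluation metrics

Entity recognition is scored with a boundary-weighted precision: with
*C* correct mentions, *B* mentions of the correct semantic type but wrong
boundaries, and *T* mentions with a wrong type (*C + B + T = N*),
boundary-only errors cost half a point:

```
P = 100 · (C + 0.5·B) / (C + B + T)
```

Relation extraction is scored with precision/recall/F over complete
triples — a prediction counts only if the relation *and both argument
mentions* (exact spans and types) are right.

## Worked example

```
$ cat fosfo.txt
Fosfomycin and amoxicillin-clavulanate appear to be effective for cystitis caused by susceptible isolates
$ medrelex extract --in fosfo.txt --out - --rdf-out store.ttl
{"doc_id": "fosfo", "relation": "treats", "pattern_id": "tr-effective-for",
 "source": {"surface": "Fosfomycin", "concept_id": "C0016832",
            "semantic_type": "Pharmacologic Substance", "category": "Treatment", ...},
 "target": {"surface": "cystitis", "concept_id": "C0010692",
            "semantic_type": "Disease or Syndrome", "category": "Problem", ...}}
{"doc_id": "fosfo", "relation": "treats", "pattern_id": "tr-effective-for",
 "source": {"surface": "amoxicillin-clavulanate", "concept_id": "C0052796", ...},
 "target": {"surface": "cystitis", ...}}
```

Both coordinated drugs are extracted as treatments of cystitis: the
treats pattern `E1 ... effective (for|against) E2` fires once per member
of the coordinated treatment phrase. The stored annotations answer
form-based queries:

```
$ medrelex query --store store.ttl --source Treatment --relation treats --target cystitis
{"sentence_text": "Fosfomycin and amoxicillin-clavulanate appear to be effective for
  cystitis caused by susceptible isolates", "relation": "treats",
 "source_surface": "Fosfomycin", "source_concept": "C0016832",
 "target_surface": "cystitis", "target_concept": "C0010692", ...}
{... "source_surface": "amoxicillin-clavulanate", "source_concept": "C0052796", ...}
```

The library API mirrors the CLI:

```python
from medrelex import recognize, extract
from medrelex.resources import default_schema, default_lexicon, default_patterns

schema = default_schema()
lexicon = default_lexicon(schema)
patterns = default_patterns(schema)
sentence = "Diazoxide was found to reduce hypoglycemia ."
mentions = recognize(sentence, lexicon, schema, doc_id="ex")
triples = extract(sentence, mentions, patterns, schema)
print([(t.source.surface, t.relation, t.target.surface) for t in triples])
# [('Diazoxide', 'treats', 'hypoglycemia')]
```

Other commands: `medrelex annotate` (mentions only), `medrelex
build-patterns` (candidate induction from seed pairs), `medrelex
evaluate` (entity + relation scoring), `medrelex gen-fixtures`
(synthetic gold corpora).

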