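# Methods

## Pipeline model and assumptions

`medrelex` is a knowledge- and pattern-based annotator. It assumes that

* medical entities can be recognized by dictionary lookup against a
  lexicon of terms and explicit surface variants (no stemming or
  derivational morphology — `amoxicillin`, `amoxycillin` and `AMOX` are
  three term entries for one concept, which keeps matching deterministic
  and auditable);
* the admissible relations between two mentions are determined by their
  semantic types through a schema of licensed, *directed* (source type,
  target type) pairs; and
* whether a licensed relation is actually asserted by a sentence can be
  decided by matching linguistic patterns with typed slots.

Segmentation runs before concept mapping. Mapping inside base noun
phrases, rather than over raw text, is the design that keeps entity
boundaries clean; mentions never cross chunk boundaries.

## Segmentation

Sentences end at `. ! ?` followed by whitespace and an uppercase letter
or digit, unless the period closes a listed abbreviation (a biomedical
abbreviation list ships with the package; `i.v.`, `e.g.`, `et al.` …).
All offsets are 0-based, half-open, character-level — unambiguous slicing
in either direction.

The tokenizer keeps internal hyphens (`amoxicillin-clavulanate` is one
token) and splits all other punctuation. POS tagging is a pluggable
interface; the shipped tagger uses closed-class word lists (determiners,
prepositions, conjunctions, modals, common verbs) plus suffix heuristics
(`-ly` adverbs, `-ed` verbs, `-ous/-ive/-al/…` adjectives), defaulting to
noun. This is deliberately shallow: it only needs to separate nouns and
pre-nominal modifiers from verbs well enough for the base-NP grammar
`DT? JJ* NN+` (noun-noun compounds absorbed by the `NN+` tail). A
suffix rule tagging `-ing` words as verbal forms was rejected because it
mis-handles the many `-ing` nominals of clinical text (*poisoning*,
*imaging*, *swelling*).

## Entity recognition

Dictionary lookup is greedy, left-to-right, longest-match-first inside
each chunk; index keys are tokenization-aware normalizations (lowercase,
NFC, collapsed whitespace), so `Rhinitis, Vasomotor` and
`rhinitis , vasomotor` index identically. Every candidate carries one
(span, concept, semantic type); filters then remove stoplisted surfaces
and types outside the allowed set (default: every type whose category is
not Other — i.e. only possible relation arguments survive).

Disambiguation — needed because one span can map to several concepts or
types — is a deterministic rule of this package's design: longest span
first (earlier start breaks span ties), then within a span the candidate
whose category comes earliest in a configurable priority
(Problem, Treatment, Test), with remaining ties broken lexicographically
on (semantic type, concept id). Any total order would do; this one is
reproducible and easy to audit. The stoplist and type filters commute
(they test disjoint fields), and enlarging the stoplist can only shrink,
enlarging the allowed types only grow, the output.

## Relation extraction

The pattern dialect: literal tokens, one `E1` and one `E2` slot
(optionally `E1[Category]`; defaults per relation — treats/prevents
Treatment→Problem, diagnoses Test→Problem, the rest Problem→Problem),
`(...)?` optional groups, `(a|b)` alternation, and `...` gaps bounded at
6 tokens (configurable). Slots may appear in either textual order; the
triple's source is always the E1 filler, so passive formulations are
written with `E2` first (`E2 induced by E1`).

Two criteria order the search, with relation order as the outer loop:
candidate relations for a pair are tried by global rank
(treats=1, prevents=2, diagnoses=3, causes=4, sign_or_symptom_of=5,
complicates=6 by default — overridable in the schema file, since the
right empirical order is corpus-dependent), and within a relation
patterns are tried by specialization degree descending (ties broken by
pattern id). The degree is the number of obligatory literal tokens:
optional groups count zero, a mandatory alternation counts the minimum
over branches. By default the first match decides a pair ("one relation
per pair"); switching that off makes per-relation decisions independent,
which is useful for recall studies and gives clean monotonicity
properties under pattern-set changes.

Matching is implemented by compiling a template to a regular expression
over the sentence's token sequence with the two mention spans collapsed
to atomic sentinel symbols. Coordination is resolved at match time:
mentions of the same category separated only by `,`/`and`/`or` form a
group, and a slot aligned with any member consumes the whole group —
this is what lets *"Fosfomycin and amoxicillin-clavulanate appear to be
effective for cystitis"* yield one treats triple per drug. The compiled
matcher is checked in the test suite against an independent brute-force
oracle that expands every optional group, alternation and gap length
exhaustively.

## Pattern construction

Corpus-selection queries follow
`<problem>/<subheading>[MAJR] AND (<t1> OR …)`, with subheadings
treats→`th`, prevents→`pc`, diagnoses→`di`; relations without an
indexing qualifier raise an explicit error, reflecting a real limitation
of subheading-based corpus focusing. No HTTP client is included: query
strings are emitted, and the corpus is read from local text or
PMC-style NXML files (title, abstract, body, in that order, markup
stripped).

Sentences are kept when they mention both concepts of a seed pair of the
target relation (once per distinct pair). Skeleton induction is
deliberately conservative because curation is manual downstream: the
inter-mention tokens become literals, determiners and numbers become
gaps, and up to 2 non-punctuation context tokens are kept on each side
(a documented default; nothing in the method fixes the window). Every
induced skeleton must compile in the pattern dialect, and induction from
sentences generated by instantiating a known template recovers a
template that matches those sentences (closure, tested).

## Evaluation

The verdicts partition predictions (C + B + T = N): exact span + type is
*correct*; a same-type gold mention overlapping by ≥1 character (the
default operationalization of "wrong boundaries"; a head-token criterion
is available) is *boundary_only*; everything else — including
predictions with no gold counterpart, which the identity forces into
this class — is a *type error*. Weighted precision is
`100·(C + 0.5B)/N`, undefined at N=0 (explicit error). Display values
are rounded half-up to 2 decimals; internal arithmetic is unrounded.
Entity recall is deliberately not computed: it would require exhaustive
gold annotation of every entity in the corpus.

Relation P/R/F uses exact triple identity (relation plus both argument
spans and types) — correct argument extraction is mandatory, matching
the needs of question-answering back-ends where precision has priority.

## Synthetic corpora

The generator instantiates pattern templates with lexicon terms
(optional groups included with probability 0.5; gaps filled with 0–2
words from a neutral filler vocabulary disjoint from the lexicon), so
gold mentions and triples are exact by construction. Term choice is
restricted to unambiguous, single-typed, non-stoplisted entries of a
type pair that licenses the pattern's relation — the conditions under
which the recognition pipeline provably recovers the planted mentions.
Distractors instantiate the classic false-positive causes: co-occurring
entities with neutral wording, another relation's wording on a type pair
that licenses nothing, and dictionary-noise stoplist traps (the packaged
lexicon deliberately contains "normal" as both a term and a stoplist
entry). The perturbation module converts exactly ⌊rate·N⌋ gold mentions
into boundary errors (one-token extension or truncation) or type errors
(a different non-Other type), seeded and collision-checked.

What passing on these fixtures shows — and does not. The fixtures are
structural stand-ins: they exercise offsets, licensing, ordering,
filtering, metric arithmetic and serialization exactly, but their
vocabulary, syntax and ambiguity are far simpler than PMC prose. Perfect
closure scores (P=R=F=100% on clean corpora) validate the machinery, not
performance on real biomedical text, which depends on lexicon coverage
and pattern inventories far larger than the packaged starter set.

## Sizes and defaults used by the shipped checks

The acceptance script reproduces the two internally consistent
boundary-weighted precision conditions at their exact error rates:
8 positive sentences (16 mentions) with 2 boundary + 6 type errors →
56.25%, and 2 positives + 1 trap (5 mentions) with 2 type errors →
60.00%. Property suites in the tests use 50-sentence corpora and 200
random pattern-matching instances — sizes at which every enumeration is
exhaustive while the whole suite stays fast on one CPU.

## Known limitations

* No negation or hedging detection; a matched pattern in a negated or
  hypothetical context still yields a triple.
* No cross-sentence relations, no coreference, no abbreviation
  expansion, no probabilistic scoring.
* The shipped schema licenses five relations between *Therapeutic or
  Preventive Procedure* and *Disease or Syndrome*
  (treats, prevents, complicates, diagnoses, causes); the last two are
  package choices and overridable in the schema file.
* The starter pattern set is illustrative (18 patterns); production use
  requires curating induced candidates per relation.
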