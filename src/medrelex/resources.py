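"""Access to the packaged starter resources (lexicon, schema, patterns...)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .knowledge import Lexicon, SeedPair, SemanticSchema, load_lexicon, load_schema, load_seed_pairs
from .relations import CompiledPattern, PatternSpec, compile_patterns, load_pattern_specs

__all__ = [
    "data_path",
    "default_abbreviations",
    "default_lexicon",
    "default_patterns",
    "default_pattern_specs",
    "default_schema",
    "default_seed_pairs",
]


def data_path(name: str) -> Path:
    path = resources.files("medrelex") / "data" / name
    return Path(str(path))


def default_schema() -> SemanticSchema:
    return load_schema(data_path("schema.yaml"))


def default_lexicon(schema: SemanticSchema | None = None) -> Lexicon:
    return load_lexicon(data_path("lexicon.yaml"), schema or default_schema())


def default_pattern_specs() -> list[PatternSpec]:
    return load_pattern_specs(data_path("patterns.yaml"))


def default_patterns(schema: SemanticSchema | None = None) -> list[CompiledPattern]:
    return compile_patterns(default_pattern_specs(), schema or default_schema())


def default_seed_pairs(lexicon: Lexicon | None = None) -> list[SeedPair]:
    lex = lexicon if lexicon is not None else default_lexicon()
    return load_seed_pairs(data_path("seeds.tsv"), lex)


def default_abbreviations() -> frozenset[str]:
    text = data_path("abbreviations.txt").read_text(encoding="utf-8")
    return frozenset(line.strip().lower() for line in text.splitlines() if line.strip())
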