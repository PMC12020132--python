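"""Tokenization contract, POS filtering, anonymization, term standardization.

Tokenizers are pluggable so that the whole pipeline runs on language-neutral,
pre-annotated token streams.  The default ``annotated`` tokenizer reads the
``surface[:base]/major[.minor]`` dialect used throughout the test corpus; a
morphological-analyzer adapter for unsegmented languages can be registered via
:func:`register_tokenizer` and mapped onto the internal closed tagset with
:func:`map_ipadic_pos`.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ._util import ConfigurationError
from .corpus import (
    PROPER_NOUN_MINORS,
    AnalyzedRecord,
    Corpus,
    RawRecord,
    Token,
    TokenizedRecord,
    parse_annotated,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tokenizer registry

_TOKENIZERS: dict[str, Callable[[str], list[Token]]] = {}


def register_tokenizer(name: str, fn: Callable[[str], list[Token]]) -> None:
    _TOKENIZERS[name] = fn


def tokenize(text: str, tokenizer: str | Callable[[str], list[Token]] = "annotated") -> list[Token]:
    """Tokenize text with a registered tokenizer (or a callable)."""
    if callable(tokenizer):
        return tokenizer(text)
    try:
        fn = _TOKENIZERS[tokenizer]
    except KeyError:
        raise ConfigurationError(
            f"unregistered tokenizer {tokenizer!r}; available: {sorted(_TOKENIZERS)}"
        ) from None
    return fn(text)


register_tokenizer("annotated", parse_annotated)

#: Mapping from ipadic-style tag names to the internal closed tagset.
_IPADIC_MAJOR = {
    "名詞": "noun",
    "動詞": "verb",
    "形容詞": "adjective",
    "副詞": "adverb",
    "感動詞": "interjection",
    "連体詞": "prenominal",
    "記号": "symbol",
    "助詞": "particle",
    "助動詞": "auxiliary_verb",
}
_IPADIC_MINOR = {
    "接尾": "suffix",
    "数": "number",
    "代名詞": "pronoun",
    "非自立": "formal_noun",
    "固有名詞-人名": "proper_noun_person",
    "固有名詞-組織": "proper_noun_org",
    "固有名詞-地域": "proper_noun_location",
    "一般": "general",
}


def map_ipadic_pos(major: str, minor: str = "一般") -> tuple[str, str]:
    """Map an ipadic-style POS pair onto the internal tagset.

    Unmapped major categories collapse to ``other`` (later dropped); unmapped
    minor categories collapse to ``general``.
    """
    return _IPADIC_MAJOR.get(major, "other"), _IPADIC_MINOR.get(minor, "general")


# ---------------------------------------------------------------------------
# POS filtering

@dataclass(frozen=True)
class PosFilterRules:
    """Which POS categories survive filtering."""

    keep_major: frozenset[str]
    drop_minor: dict[str, frozenset[str]]
    drop_major: frozenset[str]

    def __post_init__(self) -> None:
        if self.keep_major & self.drop_major:
            raise ConfigurationError("keep_major and drop_major must be disjoint")

    def keeps(self, token: Token) -> bool:
        if token.pos_major in self.drop_major:
            return False
        if token.pos_major not in self.keep_major:
            return False
        return token.pos_minor not in self.drop_minor.get(token.pos_major, frozenset())


#: Default rules: keep content words; drop suffixes/numbers/pronouns/formal
#: (non-independent) nouns, auxiliary adjectives, and all symbols, particles
#: and auxiliary verbs.
DEFAULT_RULES = PosFilterRules(
    keep_major=frozenset(
        {"noun", "verb", "adjective", "adverb", "interjection", "prenominal"}
    ),
    drop_minor={
        "noun": frozenset({"suffix", "number", "pronoun", "formal_noun", "auxiliary"}),
        "adjective": frozenset({"auxiliary_adjective"}),
    },
    drop_major=frozenset({"symbol", "particle", "auxiliary_verb"}),
)


def pos_filter(tokens: Sequence[Token], rules: PosFilterRules = DEFAULT_RULES) -> list[Token]:
    """Retain only tokens passing the POS rules (order preserved)."""
    return [t for t in tokens if rules.keeps(t)]


def anonymize(tokens: Sequence[Token], placeholder: str | None = None) -> list[Token]:
    """Remove proper-noun person/organization/location tokens.

    With ``placeholder`` set, identifiers are replaced by a redaction token
    instead of removed.
    """
    out: list[Token] = []
    for t in tokens:
        if t.pos_minor in PROPER_NOUN_MINORS:
            if placeholder is not None:
                out.append(Token(placeholder, placeholder, t.pos_major, "general"))
            continue
        else:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Standardization

def normalize_term(term: str) -> str:
    """Width (NFKC) and case normalization applied before any table lookup."""
    return unicodedata.normalize("NFKC", term).casefold()


@dataclass
class StandardizationTables:
    """Synonym, exclusion and compound-lexicon tables.

    Keys are normalized with :func:`normalize_term`; synonym values are the
    canonical terms (typically keyed to a controlled-vocabulary identifier).
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    exclusion_words: set[str] = field(default_factory=set)
    compound_lexicon: dict[tuple[str, ...], str] = field(default_factory=dict)
    vocabulary_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.synonym_map = {normalize_term(k): v for k, v in self.synonym_map.items()}
        self.exclusion_words = {normalize_term(w) for w in self.exclusion_words}
        self.compound_lexicon = {
            tuple(normalize_term(p) for p in parts): canon
            for parts, canon in self.compound_lexicon.items()
        }
        bad = {
            canon
            for canon in self.synonym_map.values()
            if normalize_term(canon) in self.exclusion_words
        }
        if bad:
            raise ConfigurationError(
                f"canonical terms also listed as exclusions: {sorted(bad)}"
            )

    @property
    def max_compound_len(self) -> int:
        return max((len(p) for p in self.compound_lexicon), default=0)


def _read_tsv(path: str | Path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_tables(
    synonyms: str | Path | None = None,
    exclusions: str | Path | None = None,
    compounds: str | Path | None = None,
) -> StandardizationTables:
    """Load the tab-separated mapping tables.

    ``synonyms.tsv``: term, canonical, vocabulary_id; ``exclusions.tsv``:
    term; ``compounds.tsv``: space-joined parts, canonical[, score].
    """
    syn: dict[str, str] = {}
    vocab: dict[str, str] = {}
    if synonyms:
        for row in _read_tsv(synonyms):
            term, canonical = row[0], row[1]
            syn[term] = canonical
            if len(row) > 2 and row[2]:
                vocab[canonical] = row[2]
    excl = {row[0] for row in _read_tsv(exclusions)} if exclusions else set()
    comp: dict[tuple[str, ...], str] = {}
    if compounds:
        for row in _read_tsv(compounds):
            parts = tuple(row[0].split())
            comp[parts] = row[1] if len(row) > 1 and row[1] else " ".join(parts)
    return StandardizationTables(syn, excl, comp, vocab)


def _is_single_alpha_or_unit(term: str) -> bool:
    # single alphabetic characters carry no meaning as analysis targets
    return len(term) == 1 and term.isalpha()


def standardize(
    tokens: Sequence[Token],
    tables: StandardizationTables,
    use_base_form: bool = True,
) -> list[str]:
    """Produce the analyzed term stream from a filtered token stream.

    1. contiguous runs matching the compound lexicon merge into single terms
       (greedy longest match, left to right);
    2. every term maps through the synonym table to its canonical form;
    3. exclusion words and single alphabetic characters are dropped.
    """
    stream = [
        normalize_term(t.base_form if use_base_form else t.surface) for t in tokens
    ]
    merged: list[str] = []
    maxlen = tables.max_compound_len
    i = 0
    n = len(stream)
    while i < n:
        hit = None
        for L in range(min(maxlen, n - i), 1, -1):
            parts = tuple(stream[i : i + L])
            if parts in tables.compound_lexicon:
                hit = (L, tables.compound_lexicon[parts])
                break
        if hit:
            L, canon = hit
            merged.append(canon)
            i += L
        else:
            merged.append(stream[i])
            i += 1
    out: list[str] = []
    for term in merged:
        term = tables.synonym_map.get(normalize_term(term), term)
        key = normalize_term(term)
        if key in tables.exclusion_words or _is_single_alpha_or_unit(key):
            continue
        out.append(term)
    return out


def standardize_corpus(
    corpus: Corpus,
    tables: StandardizationTables,
    rules: PosFilterRules = DEFAULT_RULES,
    tokenizer: str | Callable[[str], list[Token]] = "annotated",
    anonymize_identifiers: bool = True,
    use_base_form: bool = True,
) -> list[AnalyzedRecord]:
    """Run tokenize -> POS filter -> anonymize -> standardize over a corpus."""
    analyzed: list[AnalyzedRecord] = []
    for rec in corpus.records:
        toks = rec.tokens if isinstance(rec, TokenizedRecord) else tokenize(rec.text, tokenizer)
        toks = pos_filter(toks, rules)
        if anonymize_identifiers:
            toks = anonymize(toks)
        terms = standardize(toks, tables, use_base_form=use_base_form)
        analyzed.append(AnalyzedRecord(rec.record_id, rec.month, terms, rec.period))
    return analyzed


def raw_term_counts(
    corpus: Corpus,
    tokenizer: str | Callable[[str], list[Token]] = "annotated",
) -> dict[str, int]:
    """Token counts per record before filtering (the 'raw terms' statistic)."""
    counts = {}
    for rec in corpus.records:
        toks = rec.tokens if isinstance(rec, TokenizedRecord) else tokenize(rec.text, tokenizer)
        counts[rec.record_id] = len(toks)
    return counts
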