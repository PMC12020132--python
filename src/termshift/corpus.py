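"""Corpus data model and I/O.

A corpus is an ordered collection of clinical records, each tagged with a
calendar month and a study period (``pre`` / ``post``) relative to an
intervention cutoff month.  Records enter either as free text
(:class:`RawRecord`) or as pre-tokenized, part-of-speech-annotated streams
(:class:`TokenizedRecord`).  Besides the retained seed-term records, a corpus
remembers the *total* number of records per period so that share-of-total
statistics remain computable after selection.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._util import round_half_up

log = logging.getLogger(__name__)

#: Closed set of major part-of-speech categories.
POS_MAJOR = frozenset(
    {
        "noun",
        "verb",
        "adjective",
        "adverb",
        "interjection",
        "prenominal",
        "symbol",
        "particle",
        "auxiliary_verb",
        "other",
    }
)

#: Minor categories marking personal identifiers subject to anonymization.
PROPER_NOUN_MINORS = frozenset(
    {"proper_noun_person", "proper_noun_org", "proper_noun_location"}
)

#: Month at which the intervention started; records from this month on are "post".
DEFAULT_CUTOFF = "2018-04"

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


class CorpusSchemaError(ValueError):
    """A required column/key is missing or malformed in an input file."""


@dataclass(frozen=True, slots=True)
class Token:
    """One token of a record: surface form, base form and POS tags."""

    surface: str
    base_form: str = ""
    pos_major: str = "noun"
    pos_minor: str = "general"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.pos_major not in POS_MAJOR:
            raise ValueError(f"unknown pos_major {self.pos_major!r}")
        if not self.base_form:
            object.__setattr__(self, "base_form", self.surface)

    def annotated(self) -> str:
        """Serialize to the ``surface[:base]/major[.minor]`` fixture dialect."""
        s = self.surface
        if self.base_form != self.surface:
            s += f":{self.base_form}"
        s += f"/{self.pos_major}"
        if self.pos_minor != "general":
            s += f".{self.pos_minor}"
        return s


def parse_annotated_token(text: str) -> Token:
    """Parse one ``surface[:base]/major[.minor]`` token."""
    head, _, pos = text.rpartition("/")
    if not head:
        raise ValueError(f"token {text!r} lacks a '/pos' suffix")
    surface, _, base = head.partition(":")
    major, _, minor = pos.partition(".")
    return Token(surface, base or surface, major, minor or "general")


def parse_annotated(text: str) -> list[Token]:
    """Parse a whitespace-separated annotated token stream."""
    return [parse_annotated_token(t) for t in text.split()]


def validate_month(month: str, record_id: str | None = None) -> str:
    if not isinstance(month, str) or not _MONTH_RE.match(month):
        where = f" in record {record_id!r}" if record_id else ""
        raise ValueError(f"unparseable month {month!r}{where}; expected YYYY-MM")
    return month


def period_for_month(month: str, cutoff: str = DEFAULT_CUTOFF) -> str:
    """Assign the study period: ``post`` iff month >= cutoff, else ``pre``."""
    return "post" if month >= cutoff else "pre"


@dataclass(slots=True)
class RawRecord:
    """One clinical record as free text."""

    record_id: str
    month: str
    text: str
    period: str | None = None
    record_type: str | None = None


@dataclass(slots=True)
class TokenizedRecord:
    """One clinical record as an ordered, POS-annotated token stream."""

    record_id: str
    month: str
    tokens: list[Token]
    period: str | None = None
    record_type: str | None = None


@dataclass(slots=True)
class AnalyzedRecord:
    """A record reduced to its final analyzed terms (post-standardization)."""

    record_id: str
    month: str
    terms: list[str]
    period: str | None = None


@dataclass
class Corpus:
    """A sequence of records plus total per-period record counts.

    ``total_per_period`` includes records *not* containing the seed term, so
    share-of-total statistics survive seed selection.  When omitted it is
    initialized from the records themselves.
    """

    records: list
    total_per_period: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_per_period:
            counts: dict[str, int] = {}
            for r in self.records:
                counts[r.period] = counts.get(r.period, 0) + 1
            self.total_per_period = counts
        for period, total in self.total_per_period.items():
            kept = sum(1 for r in self.records if r.period == period)
            if kept > total:
                raise ValueError(
                    f"period {period!r}: {kept} retained records exceed total {total}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def periods(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.period)
        return sorted(seen)

    def subset(self, records: Iterable) -> "Corpus":
        return Corpus(list(records), dict(self.total_per_period))


# ---------------------------------------------------------------------------
# I/O

_REQUIRED = ("record_id", "text")


def _record_from_mapping(row: dict, cutoff: str) -> RawRecord | TokenizedRecord:
    for key in ("record_id",):
        if row.get(key) in (None, ""):
            raise CorpusSchemaError(f"missing required column {key!r}")
    record_id = str(row["record_id"])
    month = row.get("month")
    period = row.get("period") or None
    if month in (None, ""):
        if period is None:
            raise CorpusSchemaError(
                "missing required column 'month' (or an explicit 'period')"
            )
        month = ""
    else:
        month = validate_month(str(month), record_id)
        if period is None:
            period = period_for_month(month, cutoff)
    record_type = row.get("record_type") or None
    tokens = row.get("tokens")
    if tokens not in (None, ""):
        if isinstance(tokens, str):
            toks = parse_annotated(tokens)
        else:
            toks = [parse_annotated_token(t) for t in tokens]
        return TokenizedRecord(record_id, month, toks, period, record_type)
    if row.get("text") in (None, ""):
        raise CorpusSchemaError("missing required column 'text' (or 'tokens')")
    return RawRecord(record_id, month, str(row["text"]), period, record_type)


def read_records(
    path: str | Path,
    format: str | None = None,
    cutoff: str = DEFAULT_CUTOFF,
) -> list[RawRecord | TokenizedRecord]:
    """Read records from a JSONL or CSV file.

    The period is derived from the month and ``cutoff`` when not explicit.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusSchemaError(f"line {lineno}: invalid JSON") from exc
                records.append(_record_from_mapping(row, cutoff))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "record_id" not in reader.fieldnames:
                raise CorpusSchemaError("missing required column 'record_id'")
            for row in reader:
                records.append(_record_from_mapping(row, cutoff))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records


def write_records(records: Iterable, path: str | Path) -> None:
    """Write records as one-per-line JSONL (tokenized records use the
    annotated-stream dialect)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            row: dict = {"record_id": r.record_id, "month": r.month, "period": r.period}
            if r.record_type:
                row["record_type"] = r.record_type
            if isinstance(r, TokenizedRecord):
                row["tokens"] = " ".join(t.annotated() for t in r.tokens)
            else:
                row["text"] = r.text
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Selection

def _contains_variant(record, variants: set[str]) -> bool:
    if isinstance(record, TokenizedRecord):
        return any(
            t.base_form in variants or t.surface in variants for t in record.tokens
        )
    text = record.text
    return any(v in text for v in variants)


def select_seed_records(corpus: Corpus, seed_variants: Sequence[str]) -> Corpus:
    """Retain records containing at least one seed-term variant.

    Tokenized records match on token base/surface forms; raw records by
    substring.  Total per-period counts are carried over unchanged so that
    shares stay referenced to the full corpus.
    """
    if not seed_variants:
        raise ValueError("seed_variants must be non-empty")
    variants = set(seed_variants)
    kept = [r for r in corpus.records if _contains_variant(r, variants)]
    return corpus.subset(kept)


def exclude_record_type(corpus: Corpus, record_type: str) -> Corpus:
    """Drop records flagged with a given type (e.g. stewardship-team notes)."""
    return corpus.subset(r for r in corpus.records if r.record_type != record_type)


def filter_by_month(corpus: Corpus, exclude_from: str) -> Corpus:
    """Retain records with month strictly before ``exclude_from``."""
    validate_month(exclude_from)
    return corpus.subset(r for r in corpus.records if r.month < exclude_from)


# ---------------------------------------------------------------------------
# Summaries

def share_percent(count: int, total: int) -> float:
    """Share of total as a percentage, half-up rounded to 2 decimals."""
    return round_half_up(100.0 * count / total, 2)


def mean_terms_per_record(total_terms: int, n_records: int) -> float:
    """Mean terms per record, half-up rounded to 1 decimal (report dialect)."""
    return round_half_up(total_terms / n_records, 1)


def _mean_sd(values: Sequence[float]) -> tuple[float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class CorpusSummary:
    """Per-period descriptive statistics mirroring the study's Table-1 layout."""

    per_period: dict[str, dict]

    def to_tsv(self) -> str:
        periods = sorted(self.per_period)
        lines = ["\t".join(["statistic"] + periods)]

        def fmt_ms(ms, nd=1):
            if ms is None:
                return ""
            m, s = ms
            return f"{round_half_up(m, nd)} ± {round_half_up(s, nd)}"

        rows = [
            ("total_records", lambda s: str(s["total_records"])),
            (
                "seed_records",
                lambda s: f"{s['seed_records']} ({s['share_pct']:.2f}%)"
                if s["share_pct"] is not None
                else str(s["seed_records"]),
            ),
            ("characters_per_record", lambda s: fmt_ms(s["chars"])),
            ("raw_terms_per_record", lambda s: fmt_ms(s["raw_terms"])),
            ("analyzed_terms_per_record", lambda s: fmt_ms(s["analyzed_terms"])),
        ]
        for name, f in rows:
            lines.append("\t".join([name] + [f(self.per_period[p]) for p in periods]))
        return "\n".join(lines) + "\n"


def summarize(
    corpus: Corpus,
    analyzed: Sequence[AnalyzedRecord] | None = None,
    raw_term_counts: dict[str, int] | None = None,
) -> CorpusSummary:
    """Summarize a (seed-selected) corpus per period.

    ``analyzed`` supplies final analyzed-term streams aligned by record id;
    ``raw_term_counts`` optionally supplies pre-filter token counts per record
    (defaults to the tokenized records' own token counts).
    """
    analyzed_by_id = {a.record_id: a for a in analyzed} if analyzed else {}
    per_period: dict[str, dict] = {}
    periods = set(corpus.total_per_period) | set(corpus.periods())
    for period in sorted(periods):
        recs = [r for r in corpus.records if r.period == period]
        total = corpus.total_per_period.get(period, len(recs))
        stats: dict = {
            "total_records": total,
            "seed_records": len(recs),
            "share_pct": share_percent(len(recs), total) if total else None,
            "chars": None,
            "raw_terms": None,
            "analyzed_terms": None,
        }
        if not recs:
            log.warning("period %r has zero seed records; summary fields empty", period)
            per_period[period] = stats
            continue
        chars = [len(r.text) for r in recs if isinstance(r, RawRecord)]
        stats["chars"] = _mean_sd(chars)
        if raw_term_counts is not None:
            raw = [raw_term_counts[r.record_id] for r in recs if r.record_id in raw_term_counts]
        else:
            raw = [len(r.tokens) for r in recs if isinstance(r, TokenizedRecord)]
        stats["raw_terms"] = _mean_sd(raw)
        if analyzed_by_id:
            counts = [
                len(analyzed_by_id[r.record_id].terms)
                for r in recs
                if r.record_id in analyzed_by_id
            ]
            stats["analyzed_terms"] = _mean_sd(counts)
        per_period[period] = stats
    return CorpusSummary(per_period)
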