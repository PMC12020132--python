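"""Shared fixtures: tiny annotated corpora and mapping tables."""

from __future__ import annotations

import pytest

from termshift.corpus import Corpus, RawRecord, Token, TokenizedRecord, parse_annotated


def tok(surface: str, major: str = "noun", minor: str = "general", base: str | None = None) -> Token:
    return Token(surface, base or surface, major, minor)


@pytest.fixture
def toy_corpus() -> Corpus:
    """Five tokenized records; three contain a seed-term variant."""

    def rec(rid, month, text):
        return TokenizedRecord(rid, month, parse_annotated(text), None)

    records = [
        rec("r1", "2017-06", "antimicrobial/noun therapy/noun start/verb"),
        rec("r2", "2017-07", "renal/noun function/noun check/verb"),
        rec("r3", "2018-05", "antibiotic/noun crp/noun rising/verb"),
        rec("r4", "2019-01", "patient/noun stable/adjective"),
        rec("r5", "2020-02", "anti-infective/noun review/noun"),
    ]
    for r in records:
        r.period = "pre" if r.month < "2018-04" else "post"
    return Corpus(records)


@pytest.fixture
def tables_dir(tmp_path):
    """Standardization tables written as TSV files."""
    (tmp_path / "synonyms.tsv").write_text(
        "antibiotic\tantimicrobial\tD000900\n"
        "antibacterial\tantimicrobial\tD000900\n"
        "crp\tc-reactive protein\tD002097\n",
        encoding="utf-8",
    )
    (tmp_path / "exclusions.tsv").write_text("mg\nml\n", encoding="utf-8")
    (tmp_path / "compounds.tsv").write_text(
        "renal function\tRenal Function\n", encoding="utf-8"
    )
    return tmp_path
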