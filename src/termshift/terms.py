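"""Compound-term candidate extraction and FLR importance scoring.

Candidates are maximal contiguous runs of noun tokens.  Each candidate
``W = N1 ... NL`` gets a neighbor-connectivity score

    LR(W) = ( prod_i (FL(Ni)+1) * (FR(Ni)+1) ) ** (1 / (2L))

where ``FL(N)`` / ``FR(N)`` count noun-bigram occurrences with ``N`` as the
second / first element, and an importance score ``FLR(W) = f(W) * LR(W)``
with ``f(W)`` the candidate's corpus frequency.  Multi-part candidates with
FLR in the top percentile become the compound lexicon.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._util import ConfigurationError
from .corpus import Token
from .preprocess import normalize_term

log = logging.getLogger(__name__)

NOUN_POS = frozenset({"noun"})


@dataclass(frozen=True)
class CompoundCandidate:
    """A maximal noun run and its corpus frequency."""

    parts: tuple[str, ...]
    frequency: int

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("candidate parts must be non-empty")
        if self.frequency < 1:
            raise ValueError("candidate frequency must be >= 1")


@dataclass(frozen=True)
class TermScore:
    candidate: CompoundCandidate
    lr_score: float
    flr_score: float


def _noun_runs(tokens: Sequence[Token], use_base_form: bool = True) -> Iterable[tuple[str, ...]]:
    run: list[str] = []
    for t in tokens:
        if t.pos_major in NOUN_POS:
            run.append(normalize_term(t.base_form if use_base_form else t.surface))
        elif run:
            yield tuple(run)
            run = []
    if run:
        yield tuple(run)


def extract_candidates(
    token_records: Iterable[Sequence[Token]],
    use_base_form: bool = True,
) -> list[CompoundCandidate]:
    """Collect every maximal noun run (length >= 1) with corpus frequency."""
    counts: Counter[tuple[str, ...]] = Counter()
    for tokens in token_records:
        counts.update(_noun_runs(tokens, use_base_form))
    return [
        CompoundCandidate(parts, freq)
        for parts, freq in sorted(counts.items())
    ]


def bigram_neighbor_counts(
    candidates: Iterable[CompoundCandidate],
) -> tuple[Counter, Counter]:
    """Left/right neighbor counts from within-run noun bigrams.

    All adjacent noun pairs occur inside maximal noun runs, so the bigram
    statistics are fully recoverable from the candidates themselves: a run
    ``N1..NL`` of frequency f contributes f to FR(Ni) and FL(Ni+1) for each
    internal bigram.
    """
    fl: Counter[str] = Counter()
    fr: Counter[str] = Counter()
    for cand in candidates:
        for left, right in zip(cand.parts, cand.parts[1:]):
            fr[left] += cand.frequency
            fl[right] += cand.frequency
    return fl, fr


def score_lr(candidates: Sequence[CompoundCandidate]) -> list[TermScore]:
    """Score every candidate with the geometric-mean LR and FLR = f * LR."""
    fl, fr = bigram_neighbor_counts(candidates)
    scores = []
    for cand in candidates:
        log_sum = sum(
            math.log((fl[p] + 1.0) * (fr[p] + 1.0)) for p in cand.parts
        )
        lr = math.exp(log_sum / (2.0 * len(cand.parts)))
        scores.append(TermScore(cand, lr, cand.frequency * lr))
    return scores


def select_top_percentile(
    scores: Sequence[TermScore],
    p: float = 0.05,
    min_parts: int = 2,
) -> list[TermScore]:
    """Select multi-part candidates whose FLR reaches the top-``p`` fraction.

    The threshold is the ``ceil(p * N)``-th largest FLR over *all* candidates;
    candidates tied at the threshold are all included.
    """
    if not scores:
        raise ConfigurationError("scores must be non-empty")
    if not (0.0 < p < 1.0):
        raise ConfigurationError(f"top percentile p={p} must lie in (0, 1)")
    ordered = sorted(s.flr_score for s in scores)
    k = math.ceil(p * len(ordered))
    threshold = ordered[len(ordered) - k]
    selected = [
        s
        for s in scores
        if s.flr_score >= threshold and len(s.candidate.parts) >= min_parts
    ]
    selected.sort(key=lambda s: (-s.flr_score, s.candidate.parts))
    log.info(
        "compound selection: %d of %d candidates at FLR >= %.4g",
        len(selected),
        len(scores),
        threshold,
    )
    return selected


def write_compounds_tsv(selected: Sequence[TermScore], path: str | Path) -> None:
    """Write the compound lexicon (parts, canonical form, FLR), score-sorted."""
    lines = [
        "\t".join(
            [" ".join(s.candidate.parts), " ".join(s.candidate.parts), f"{s.flr_score:.6g}"]
        )
        for s in selected
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
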