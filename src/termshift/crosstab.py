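"""Ward clustering of network terms and pre/post association statistics.

Terms from the per-period networks are clustered hierarchically on the
1 − Dice dissimilarity (Ward's minimum-variance criterion applied directly to
the precomputed matrix via the Lance–Williams recurrence), the dendrogram is
cut at k = 10% of the term count, and each cluster is cross-tabulated between
periods at the record level: a record "contains" a cluster if it contains at
least one member term.  Association is summarized by the post/pre odds ratio
with a Wald 95% CI and a two-sided Fisher exact p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from ._util import round_half_up
from .network import IncidenceMatrix, dice_matrix

log = logging.getLogger(__name__)

Z975 = 1.959963984540054  # standard normal 97.5% quantile


# ---------------------------------------------------------------------------
# Ward clustering

def dissimilarity_matrix(matrix: IncidenceMatrix, terms: Sequence[str]) -> pd.DataFrame:
    """1 − Dice over the pooled record set, restricted to ``terms``."""
    D = dice_matrix(matrix.restrict_terms(terms))
    out = 1.0 - D
    np.fill_diagonal(out.values, 0.0)
    return out


def ward_cluster(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Ward linkage on a precomputed symmetric dissimilarity matrix."""
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if D.shape[0] < 2:
        raise ValueError("need at least two terms to cluster")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    return linkage(squareform(D, checks=False), method="ward")


@dataclass
class ClusterAssignment:
    """Term → cluster id (1..k) from a dendrogram cut."""

    mapping: dict[str, int]
    k: int
    names: dict[int, str] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return sorted(t for t, c in self.mapping.items() if c == cluster_id)

    def clusters(self) -> list[int]:
        return sorted(set(self.mapping.values()))

    def label(self, cluster_id: int) -> str:
        return self.names.get(cluster_id, f"cluster_{cluster_id}")


def cut_clusters(
    dendrogram: np.ndarray,
    terms: Sequence[str],
    fraction: float = 0.10,
    k_override: int | None = None,
) -> ClusterAssignment:
    """Cut the dendrogram into k = max(2, round(fraction · T)) clusters.

    Rounding is half-up; ``k_override`` replaces the rule entirely.
    """
    T = len(terms)
    k = k_override if k_override is not None else max(2, int(round_half_up(fraction * T)))
    if k > T:
        raise ValueError(f"requested k={k} exceeds term count T={T}")
    labels = fcluster(dendrogram, t=k, criterion="maxclust")
    mapping = {term: int(lab) for term, lab in zip(terms, labels)}
    got = len(set(mapping.values()))
    if got != k:
        log.warning("dendrogram cut produced %d clusters (requested %d)", got, k)
    return ClusterAssignment(mapping, got)


# ---------------------------------------------------------------------------
# Record-level cluster incidence and contingency tables

def record_cluster_incidence(
    matrix: IncidenceMatrix, assignment: ClusterAssignment
) -> tuple[list[int], np.ndarray]:
    """Binary records × clusters structure: 1 iff >= 1 member term present."""
    cluster_ids = assignment.clusters()
    Y = np.zeros((matrix.n_records, len(cluster_ids)), dtype=np.uint8)
    for j, cid in enumerate(cluster_ids):
        members = [t for t in assignment.members(cid) if t in matrix.terms]
        if not members:
            raise ValueError(f"cluster {cid} has no terms in the vocabulary")
        cols = np.column_stack([matrix.column(t) for t in members])
        Y[:, j] = cols.any(axis=1)
    return cluster_ids, Y


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table: a/b = post with/without, c/d = pre with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_post(self) -> int:
        return self.a + self.b

    @property
    def n_pre(self) -> int:
        return self.c + self.d


def crosstab(
    incidence: tuple[list[int], np.ndarray], periods: Sequence[str]
) -> dict[int, ContingencyTable]:
    """Per-cluster contingency tables of cluster presence by period."""
    cluster_ids, Y = incidence
    periods = np.asarray(periods)
    post = periods == "post"
    pre = periods == "pre"
    if not post.any() or not pre.any():
        raise ValueError("both 'pre' and 'post' periods must be present")
    out = {}
    for j, cid in enumerate(cluster_ids):
        col = Y[:, j].astype(bool)
        a = int((col & post).sum())
        c = int((col & pre).sum())
        out[cid] = ContingencyTable(a, int(post.sum()) - a, c, int(pre.sum()) - c)
    return out


# ---------------------------------------------------------------------------
# Association statistics

@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


def odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """Post/pre odds ratio ad/(bc) with the Wald 95% CI.

    A zero cell triggers the Haldane–Anscombe +0.5 correction (flagged);
    two zero cells in a cross pattern leave the OR undefined (NaN).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        log.warning("odds ratio undefined for cross-pattern zeros %s", table)
        return OddsRatioResult(math.nan, math.nan, math.nan, False)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        log.info("Haldane–Anscombe correction applied to %s", table)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        or_, or_ * math.exp(-Z975 * se), or_ * math.exp(Z975 * se), corrected
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one; a relative tolerance of 1e-12 guards
    floating-point ties.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    for x in (a, b, c, d):
        if not float(x).is_integer():
            raise ValueError("Fisher exact test requires integer cells")
    N = a + b + c + d
    K = a + c  # margin: records containing the cluster
    n = a + b  # margin: post-period records
    if N == 0:
        return 1.0
    support = np.arange(max(0, n - (N - K)), min(n, K) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Results assembly

@dataclass
class AssociationResult:
    cluster_id: int
    name: str
    table: ContingencyTable
    odds: OddsRatioResult
    p_value: float

    @property
    def pre_pct(self) -> float:
        return round_half_up(100.0 * self.table.c / self.table.n_pre, 1)

    @property
    def post_pct(self) -> float:
        return round_half_up(100.0 * self.table.a / self.table.n_post, 1)


def associate(
    assignment: ClusterAssignment, tables: dict[int, ContingencyTable]
) -> list[AssociationResult]:
    """Compute OR + CI + Fisher p for every cluster, in cluster-id order."""
    return [
        AssociationResult(
            cid, assignment.label(cid), tables[cid], odds_ratio(tables[cid]), fisher_exact(tables[cid])
        )
        for cid in assignment.clusters()
    ]


def _fmt_p(p: float) -> str:
    return "< 0.01" if p < 0.01 else f"{round_half_up(p, 2):.2f}"


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Report table: one row per cluster with n (%), OR (CI) and p."""
    rows = []
    for r in results:
        o = r.odds
        if math.isnan(o.odds_ratio):
            or_str = "undefined"
        else:
            or_str = (
                f"{round_half_up(o.odds_ratio, 2):.2f} "
                f"({round_half_up(o.ci_low, 2):.2f} - {round_half_up(o.ci_high, 2):.2f})"
            )
        rows.append(
            {
                "cluster": r.name,
                "pre": f"{r.table.c:,} ({r.pre_pct})",
                "post": f"{r.table.a:,} ({r.post_pct})",
                "odds_ratio_95ci": or_str,
                "p_value": _fmt_p(r.p_value),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "pre", "post", "odds_ratio_95ci", "p_value"])


def results_json(results: Sequence[AssociationResult]) -> list[dict]:
    """Raw cells and unrounded statistics for machine consumption."""
    return [
        {
            "cluster_id": r.cluster_id,
            "name": r.name,
            "cells": {"a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d},
            "odds_ratio": r.odds.odds_ratio,
            "ci_low": r.odds.ci_low,
            "ci_high": r.odds.ci_high,
            "haldane_corrected": r.odds.corrected,
            "p_value": r.p_value,
        }
        for r in results
    ]
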