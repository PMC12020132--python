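"""Incidence matrix, Dice coefficients and the seed-centered network.

Co-occurrence between two terms is measured at the record level with the
Dice coefficient 2|A∩B| / (|A|+|B|) over the sets of records containing each
term.  The network keeps every term pair with Dice >= θ and is restricted to
the connected component containing the seed term; a maximum-weight spanning
tree gives the display backbone, and Louvain modularity optimization yields
term communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.utils import UnionFind

from ._util import round_half_up
from .corpus import AnalyzedRecord

log = logging.getLogger(__name__)

DEFAULT_THETA = 0.3


@dataclass
class IncidenceMatrix:
    """Binary records × terms presence structure.

    ``X[r, t] = 1`` iff term ``t`` occurs at least once in record ``r``
    (multiplicity ignored).  Column sums are term record-frequencies.
    """

    record_ids: list[str]
    terms: list[str]
    X: np.ndarray
    periods: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.record_ids), len(self.terms)):
            raise ValueError("presence matrix shape mismatch")
        self._index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    def column(self, term: str) -> np.ndarray:
        return self.X[:, self._index[term]]

    def term_frequency(self, term: str) -> int:
        return int(self.column(term).sum())

    def frequencies(self) -> dict[str, int]:
        sums = self.X.sum(axis=0)
        return {t: int(sums[i]) for t, i in self._index.items()}

    def for_period(self, period: str) -> "IncidenceMatrix":
        mask = [p == period for p in self.periods]
        idx = np.flatnonzero(mask)
        return IncidenceMatrix(
            [self.record_ids[i] for i in idx],
            list(self.terms),
            self.X[idx],
            [period] * len(idx),
        )

    def restrict_terms(self, terms: Sequence[str]) -> "IncidenceMatrix":
        cols = [self._index[t] for t in terms]
        return IncidenceMatrix(
            list(self.record_ids), list(terms), self.X[:, cols], list(self.periods)
        )


def build_incidence(analyzed: Sequence[AnalyzedRecord]) -> IncidenceMatrix:
    """Binarize analyzed term streams into a records × terms matrix."""
    vocab = sorted({t for rec in analyzed for t in rec.terms})
    if not vocab:
        raise ValueError("empty vocabulary: no analyzed terms in corpus")
    index = {t: i for i, t in enumerate(vocab)}
    X = np.zeros((len(analyzed), len(vocab)), dtype=np.uint8)
    for r, rec in enumerate(analyzed):
        for term in rec.terms:
            X[r, index[term]] = 1
    return IncidenceMatrix(
        [r.record_id for r in analyzed], vocab, X, [r.period for r in analyzed]
    )


# ---------------------------------------------------------------------------
# Dice

def dice(matrix: IncidenceMatrix, a: str, b: str) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) over record sets."""
    ca, cb = matrix.column(a), matrix.column(b)
    denom = int(ca.sum()) + int(cb.sum())
    if denom == 0:
        log.warning("dice(%r, %r): both terms absent; returning 0", a, b)
        return 0.0
    inter = int((ca & cb).sum())
    return 2.0 * inter / denom


def dice_matrix(matrix: IncidenceMatrix) -> pd.DataFrame:
    """All pairwise Dice coefficients as a symmetric DataFrame."""
    # sparse product: vocabularies are wide but records are short
    from scipy import sparse

    Xs = sparse.csr_matrix(matrix.X.astype(np.int64))
    inter = (Xs.T @ Xs).toarray()
    freq = np.diag(inter).astype(float)
    denom = freq[:, None] + freq[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, 2.0 * inter / np.maximum(denom, 1), 0.0)
    return pd.DataFrame(D, index=matrix.terms, columns=matrix.terms)


def min_frequency_at_threshold(n: int, theta: float = DEFAULT_THETA) -> int:
    """Smallest frequency f with 2f/(n+f) >= θ on a seed-selected corpus."""
    return int(np.ceil(theta * n / (2.0 - theta)))


def seed_cooccurring_terms(
    matrix: IncidenceMatrix,
    seed: str,
    theta: float = DEFAULT_THETA,
) -> pd.DataFrame:
    """Table of terms directly co-occurring with the seed at Dice >= θ.

    Columns: term, frequency, share_pct (of records, 1 decimal), dice
    (3 decimals, half-up); rows sorted alphabetically.
    """
    n = matrix.n_records
    rows = []
    for term in matrix.terms:
        if term == seed:
            continue
        d = dice(matrix, seed, term)
        if d >= theta:
            f = matrix.term_frequency(term)
            rows.append(
                {
                    "term": term,
                    "frequency": f,
                    "share_pct": round_half_up(100.0 * f / n, 1),
                    "dice": round_half_up(d, 3),
                }
            )
    return pd.DataFrame(rows, columns=["term", "frequency", "share_pct", "dice"])


# ---------------------------------------------------------------------------
# Network construction

def build_network(
    matrix: IncidenceMatrix,
    seed: str,
    theta: float = DEFAULT_THETA,
) -> nx.Graph:
    """Thresholded Dice network restricted to the seed's connected component.

    Edges connect *any* term pair (not only seed pairs) with Dice >= θ, so
    terms linked to the seed only through intermediaries stay in the network.
    """
    if seed not in matrix.terms:
        raise ValueError(f"seed term {seed!r} not in vocabulary")
    D = dice_matrix(matrix).to_numpy()
    terms = matrix.terms
    G = nx.Graph(seed=seed, theta=theta)
    freqs = matrix.frequencies()
    for t in terms:
        G.add_node(t, frequency=freqs[t])
    iu, ju = np.triu_indices(len(terms), k=1)
    keep = D[iu, ju] >= theta
    for i, j in zip(iu[keep], ju[keep]):
        G.add_edge(terms[i], terms[j], dice=float(D[i, j]))
    component = nx.node_connected_component(G, seed)
    if len(component) == 1:
        log.warning("seed %r is isolated at theta=%s", seed, theta)
    H = G.subgraph(component).copy()
    H.graph.update(seed=seed, theta=theta)
    return H


def max_spanning_tree(network: nx.Graph) -> nx.Graph:
    """Spanning tree maximizing total Dice weight (Kruskal).

    Ties broken lexicographically by edge endpoints, so the result is
    deterministic.  Equivalent to the minimum spanning tree under 1 − Dice.
    """
    if network.number_of_nodes() > 1 and not nx.is_connected(network):
        raise ValueError("max_spanning_tree requires a connected network")
    edges = sorted(
        (tuple(sorted((u, v))) + (d["dice"],) for u, v, d in network.edges(data=True)),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    T = nx.Graph(**network.graph)
    T.add_nodes_from(network.nodes(data=True))
    uf = UnionFind(network.nodes)
    for u, v, w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            T.add_edge(u, v, dice=w)
    return T


# ---------------------------------------------------------------------------
# Communities

@dataclass
class CommunityPartition:
    """Term → community id mapping with the partition's modularity."""

    mapping: dict[str, int]
    modularity: float

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for term, cid in self.mapping.items():
            out.setdefault(cid, set()).add(term)
        return [out[c] for c in sorted(out)]


def detect_communities(network: nx.Graph, random_seed: int = 0) -> CommunityPartition:
    """Louvain greedy modularity optimization on Dice-weighted edges.

    Deterministic for a fixed ``random_seed``; community ids are assigned in
    order of each community's lexicographically smallest member.
    """
    if network.number_of_edges() == 0:
        mapping = {n: i for i, n in enumerate(sorted(network.nodes))}
        return CommunityPartition(mapping, 0.0)
    comms = nx.community.louvain_communities(
        network, weight="dice", resolution=1.0, seed=random_seed
    )
    comms = sorted(comms, key=lambda c: min(c))
    mapping = {term: cid for cid, comm in enumerate(comms) for term in comm}
    q = nx.community.modularity(network, comms, weight="dice")
    log.info("detected %d communities (modularity %.4f)", len(comms), q)
    return CommunityPartition(mapping, float(q))


# ---------------------------------------------------------------------------
# Export

def export_graphml(
    network: nx.Graph,
    path: str | Path,
    partition: CommunityPartition | None = None,
) -> None:
    """Write GraphML with node frequency/community and edge dice attributes."""
    G = network.copy()
    if partition is not None:
        for node in G.nodes:
            if node in partition.mapping:
                G.nodes[node]["community"] = int(partition.mapping[node])
    try:
        nx.write_graphml(G, str(path))
    except OSError as exc:
        raise OSError(f"failed to write GraphML to {path}: {exc}") from exc


def load_graphml(path: str | Path) -> nx.Graph:
    G = nx.read_graphml(str(path))
    return nx.relabel_nodes(G, {n: str(n) for n in G.nodes})
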