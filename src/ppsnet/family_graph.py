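"""Weighted protein-family similarity graphs and their thresholded views.

Each protein family is one undirected graph: vertices are the family's
training sequences, edge weights are EB-scores.  The graph pyramid is
the nested ladder of unweighted views obtained by pruning edges whose
weight falls below an ascending threshold; an edge whose weight exactly
equals the threshold survives (Heaviside boundary, H(0) = 1).  A stored
weight of 0 means "no edge" at every level, including t = 0, matching
the missing-pair convention of the similarity table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityTable

__all__ = [
    "FamilyGraph",
    "LabelMultiset",
    "QueryAttachment",
    "ThresholdView",
    "attach_query",
    "build_family_graph",
    "mode_labels",
    "multiset_sum",
    "threshold_view",
]


@dataclass(frozen=True)
class FamilyGraph:
    """One family's weighted undirected similarity graph.

    ``weights`` is a symmetric N x N matrix of EB-scores with a zero
    diagonal; vertex order is the (stable) insertion order of
    ``vertices``, so adjacency matrices are reproducible.
    """

    label: str
    vertices: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.vertices)
        if n < 1:
            raise ValueError("a family needs at least one vertex")
        if len(set(self.vertices)) != n:
            raise ValueError(f"duplicate vertex ids in family {self.label!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("edge weights must be nonnegative")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def max_weight(self) -> float:
        return float(self.weights.max(initial=0.0))


@dataclass(frozen=True)
class ThresholdView:
    """Unweighted view of a family graph at pruning threshold ``t``.

    ``adjacency[i, j] = 1`` iff ``weights[i, j] >= t`` and the weight is
    positive and ``i != j``.
    """

    parent: FamilyGraph
    t: float
    adjacency: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class QueryAttachment:
    """EB-scores of one query against every vertex of one family graph."""

    query_id: str
    eb_to_member: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.eb_to_member, dtype=float)
        if v.ndim != 1:
            raise ValueError("eb_to_member must be a vector")
        if np.any(v < 0):
            raise ValueError("EB-scores must be nonnegative")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "eb_to_member", v)


def build_family_graph(label: str, members: list[str], table: SimilarityTable) -> FamilyGraph:
    """Assemble a family graph from a member list and a similarity table.

    Missing pairs get weight 0 (no edge); member order fixes the vertex
    order of the weight matrix.
    """
    if not members:
        raise ValueError("members must be nonempty")
    if len(set(members)) != len(members):
        raise ValueError("duplicate member ids")
    n = len(members)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = table.get(members[i], members[j])
    return FamilyGraph(label, tuple(members), w)


def threshold_view(graph: FamilyGraph, t: float) -> ThresholdView:
    """Prune edges below ``t``; ties survive (H(0) = 1); t = 0 keeps the
    full positive-weight edge set."""
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    w = graph.weights
    adj = ((w >= t) & (w > 0)).astype(np.int8)
    return ThresholdView(graph, float(t), adj)


def attachment_from_table(graph: FamilyGraph, query_id: str,
                          table: SimilarityTable) -> QueryAttachment:
    """Look up the query's EB-score to every vertex of ``graph``."""
    vec = np.array([table.get(query_id, v) for v in graph.vertices])
    return QueryAttachment(query_id, vec)


def attach_query(graph: FamilyGraph, attachment: QueryAttachment) -> FamilyGraph:
    """Return a new (N+1)-vertex graph with the query as the last vertex.

    The input graph is never mutated; dropping the last row/column of
    the result recovers the original weights exactly.
    """
    if attachment.eb_to_member.shape[0] != graph.n_vertices:
        raise ValueError(
            f"attachment length {attachment.eb_to_member.shape[0]} != "
            f"family size {graph.n_vertices}"
        )
    if attachment.query_id in graph.vertices:
        raise ValueError(f"query id {attachment.query_id!r} already in family {graph.label!r}")
    n = graph.n_vertices
    w = np.zeros((n + 1, n + 1))
    w[:n, :n] = graph.weights
    w[n, :n] = attachment.eb_to_member
    w[:n, n] = attachment.eb_to_member
    return FamilyGraph(graph.label, graph.vertices + (attachment.query_id,), w)


# ---------------------------------------------------------------------------
# Family membership TSV (`seq_id <TAB> family_id`)

def read_families_tsv(stream) -> dict[str, str]:
    """Read a sequence -> family map; a `seq_id  family_id` header is optional."""
    members: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
        if lineno == 1 and cols[0].strip() == "seq_id":
            continue
        if cols[0] in members:
            raise ValueError(f"line {lineno}: duplicate sequence id {cols[0]!r}")
        members[cols[0]] = cols[1]
    return members


def write_families_tsv(stream, members: dict[str, str]) -> None:
    stream.write("seq_id\tfamily_id\n")
    for sid, fam in sorted(members.items()):
        stream.write(f"{sid}\t{fam}\n")


# ---------------------------------------------------------------------------
# Label multisets (vote bookkeeping)

class LabelMultiset:
    """Multiset of class labels; the currency of the voting scheme."""

    def __init__(self, labels=()) -> None:
        self._counts = Counter(labels)

    @property
    def counts(self) -> Counter:
        return Counter(self._counts)

    def __len__(self) -> int:
        return sum(self._counts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMultiset):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        items = sorted(self._counts.elements())
        return f"LabelMultiset({items!r})"


def multiset_sum(s1: LabelMultiset, s2: LabelMultiset) -> LabelMultiset:
    """Multiset sum: multiplicities add, so |S1 (+) S2| = |S1| + |S2|."""
    out = LabelMultiset()
    out._counts = s1._counts + s2._counts
    return out


def mode_labels(s: LabelMultiset) -> set:
    """All labels attaining the maximal multiplicity.

    Returning the full argmax set lets callers detect indecisive votes
    (two or more labels tied at the top).
    """
    if len(s) == 0:
        raise ValueError("mode of an empty multiset: no votes were cast")
    top = max(s._counts.values())
    return {label for label, c in s._counts.items() if c == top}
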