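"""Graph-structured features (GSF) and their query-induced deltas.

Five scalar features summarise a thresholded family graph:

AC  average clustering coefficient — mean over vertices of the edge
    density among each vertex's neighbours; modularity probe.
RC  rich-club coefficient phi(r) — edge density among vertices of degree
    strictly greater than r; hub-interconnection probe.
SM  star-motif count — number of vertices of degree >= p (hubs of
    "power" at least p).
TR  triangle count — trace(A^3)/6 on the binary adjacency.
GE  graph energy — sum of absolute adjacency eigenvalues; a spectral
    measure of how much structure (spread) the graph carries.

Classification looks at how each feature CHANGES when a query vertex is
attached to the family graph: a query that belongs tightens the family's
structure, one that does not leaves it untouched.  All deltas are
"augmented minus original" at the same threshold.

Conventions for degenerate cases: a vertex with fewer than two
neighbours contributes clustering 0; phi(r) is 0 when fewer than two
vertices exceed degree r.  Both keep the features inside [0, 1].
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .family_graph import FamilyGraph, QueryAttachment, ThresholdView, attach_query, threshold_view

__all__ = [
    "FeatureKind",
    "avg_clustering",
    "clustering_coefficients",
    "degrees",
    "delta_ac",
    "delta_ge",
    "delta_rc",
    "delta_sm",
    "delta_tr",
    "graph_energy",
    "rich_club",
    "star_motifs",
    "triangles",
]


class FeatureKind(str, Enum):
    """The five graph-structured features."""

    AC = "AC"
    RC = "RC"
    SM = "SM"
    TR = "TR"
    GE = "GE"


def degrees(view: ThresholdView) -> np.ndarray:
    return np.asarray(view.adjacency.sum(axis=1), dtype=np.int64)


def clustering_coefficients(view: ThresholdView) -> np.ndarray:
    """Per-vertex clustering coefficient C_n = 2*E_n / (N_n (N_n - 1)).

    E_n is the number of edges among the N_n neighbours of n; vertices
    with fewer than two neighbours get C_n = 0.
    """
    adj = view.adjacency.astype(np.int64)
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    # closed triangles through each vertex: diag(A^3) / 2
    closed = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    coeffs = np.zeros(n)
    mask = deg >= 2
    coeffs[mask] = 2.0 * closed[mask] / (deg[mask] * (deg[mask] - 1))
    return coeffs


def avg_clustering(view: ThresholdView) -> float:
    """Average clustering coefficient AC in [0, 1] (mean over all vertices)."""
    return float(clustering_coefficients(view).mean())


def rich_club(view: ThresholdView, r: int) -> float:
    """Rich-club coefficient phi(r): edge density among vertices of
    degree > r; 0 when fewer than two such vertices exist."""
    if r < 0:
        raise ValueError(f"degree cut r must be nonnegative, got {r}")
    adj = view.adjacency
    rich = degrees(view) > r
    n_rich = int(rich.sum())
    if n_rich < 2:
        return 0.0
    e_rich = int(adj[np.ix_(rich, rich)].sum()) // 2
    return 2.0 * e_rich / (n_rich * (n_rich - 1))


def star_motifs(view: ThresholdView, p: int) -> int:
    """Number of star motifs of power >= p, i.e. vertices of degree >= p.

    Counting "at least p" rather than "exactly p" makes the count
    monotone under query attachment: a query can only strengthen hubs.
    """
    if p < 1:
        raise ValueError(f"star power p must be a positive integer, got {p}")
    return int((degrees(view) >= p).sum())


def triangles(view: ThresholdView) -> int:
    """Exact triangle count trace(A^3)/6 on the binary adjacency."""
    adj = view.adjacency.astype(np.int64)
    tr = int(np.einsum("ij,jk,ki->", adj, adj, adj))
    if tr % 6 != 0:
        raise ValueError("trace(A^3) not divisible by 6: adjacency invariant broken")
    return tr // 6


def graph_energy(view: ThresholdView, *, weighted: bool = False) -> float:
    """Graph energy: sum of absolute eigenvalues of the adjacency.

    Computed on the binary adjacency of the view by default, consistent
    with the binary matrix used for triangle counting; ``weighted=True``
    uses the surviving EB-weights instead (the geometric "spread"
    reading).  Zero iff the view has no edges.
    """
    if weighted:
        w = view.parent.weights
        mat = np.where(view.adjacency > 0, w, 0.0)
    else:
        mat = view.adjacency.astype(float)
    if not mat.any():
        return 0.0
    return float(np.abs(np.linalg.eigvalsh(mat)).sum())


# ---------------------------------------------------------------------------
# Query-induced deltas

def _views(graph: FamilyGraph, attachment: QueryAttachment, t: float):
    augmented = attach_query(graph, attachment)
    return threshold_view(graph, t), threshold_view(augmented, t)


def delta_ac(graph: FamilyGraph, attachment: QueryAttachment, t: float) -> float:
    """Change in AC when the query joins the family at threshold t (may be < 0)."""
    before, after = _views(graph, attachment, t)
    return avg_clustering(after) - avg_clustering(before)


def delta_rc(graph: FamilyGraph, attachment: QueryAttachment, t: float, r: int) -> float:
    """Change in phi(r) when the query joins the family at threshold t."""
    before, after = _views(graph, attachment, t)
    return rich_club(after, r) - rich_club(before, r)


def delta_sm(graph: FamilyGraph, attachment: QueryAttachment, t: float, p: int) -> int:
    """Change in the star-motif count; nonnegative under the >= p convention."""
    before, after = _views(graph, attachment, t)
    return star_motifs(after, p) - star_motifs(before, p)


def delta_tr(graph: FamilyGraph, attachment: QueryAttachment, t: float) -> int:
    """Number of new triangles the query closes at threshold t (>= 0)."""
    before, after = _views(graph, attachment, t)
    return triangles(after) - triangles(before)


def delta_ge(graph: FamilyGraph, attachment: QueryAttachment, t: float,
             *, weighted: bool = False) -> float:
    """Change in graph energy; the classifier's final arbiter maximises this."""
    before, after = _views(graph, attachment, t)
    return graph_energy(after, weighted=weighted) - graph_energy(before, weighted=weighted)


def feature_delta(kind: FeatureKind, graph: FamilyGraph, attachment: QueryAttachment,
                  t: float, *, r: int = 1, p: int = 2, weighted_ge: bool = False) -> float:
    """Dispatch a delta computation by feature kind."""
    if kind is FeatureKind.AC:
        return delta_ac(graph, attachment, t)
    if kind is FeatureKind.RC:
        return delta_rc(graph, attachment, t, r)
    if kind is FeatureKind.SM:
        return float(delta_sm(graph, attachment, t, p))
    if kind is FeatureKind.TR:
        return float(delta_tr(graph, attachment, t))
    if kind is FeatureKind.GE:
        return delta_ge(graph, attachment, t, weighted=weighted_ge)
    raise ValueError(f"unknown feature kind {kind!r}")
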