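"""Synthetic benchmarks and concrete worked-example fixtures.

Real protein-family similarity networks have two salient traits this
generator emulates: (i) intra-family EB-scores are much larger than the
sporadic inter-family ones, and (ii) edges concentrate on a few hub
sequences (the rich-gets-richer topology that preferential attachment
produces).  Scores are drawn log-normally — EB-scores are products of a
log E-value and a bit-score, and their empirical spread is heavy-tailed
— with log-scale means ``mu_in``/``mu_out`` and common spread ``sigma``.

The score-level generator is the default test path: it produces a
similarity table directly, with a held-out query set, so no alignment
is needed.  The sequence-level generator emits FASTA-able records (one
random ancestor per family, members mutated from it) to exercise the
alignment route end to end.

The ``fixture_*`` functions build the small illustrative graphs used in
the documentation examples, with unit edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family_graph import FamilyGraph, QueryAttachment, build_family_graph
from .gsf import FeatureKind
from .pyramid import PyramidConfig, TrainedModel
from .similarity import SimilarityTable

__all__ = [
    "SimSpec",
    "fixture_clustered_hub",
    "fixture_star_vs_triangle",
    "fixture_pyramid_demo",
    "simulate_score_network",
    "simulate_sequences",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic family-network generator.

    ``mu_in``/``mu_out`` are log-scale means of intra-/inter-family
    EB-scores and ``sigma`` the shared log-scale spread; the defaults
    put four sigma between them, a cleanly separable benchmark.
    ``hub_gamma`` controls preferential attachment when thinning
    intra-family edges to ``edge_keep_frac`` (0 = uniform thinning);
    ``cross_frac`` is the fraction of inter-family pairs that receive a
    nonzero (weak) score.  ``holdout_frac`` of each family's members are
    withheld as queries.  Everything is a pure function of the spec,
    seed included.
    """

    n_families: int = 20
    family_size: int = 30
    mu_in: float = 6.0
    mu_out: float = 5.0
    sigma: float = 0.25
    hub_gamma: float = 1.0
    edge_keep_frac: float = 0.9
    cross_frac: float = 0.05
    holdout_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 2:
            raise ValueError("need >= 1 families of >= 2 members")
        if self.mu_in <= self.mu_out:
            raise ValueError("mu_in must exceed mu_out for a separable benchmark")
        if not (0 < self.edge_keep_frac <= 1):
            raise ValueError("edge_keep_frac must be in (0, 1]")
        if not (0 <= self.cross_frac <= 1):
            raise ValueError("cross_frac must be in [0, 1]")
        if not (0 < self.holdout_frac < 1):
            raise ValueError("holdout_frac must be in (0, 1)")
        if self.hub_gamma < 0 or self.sigma <= 0:
            raise ValueError("hub_gamma >= 0 and sigma > 0 required")


def _preferential_edges(n: int, keep_frac: float, gamma: float,
                        rng: np.random.Generator) -> list[tuple[int, int]]:
    """Choose ``keep_frac`` of the n-clique's edges, preferring pairs whose
    endpoints already carry many edges (rich-gets-richer)."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_keep = max(1, round(keep_frac * len(pairs)))
    if n_keep >= len(pairs):
        return pairs
    deg = np.zeros(n)
    remaining = list(pairs)
    chosen: list[tuple[int, int]] = []
    for _ in range(n_keep):
        w = np.array([((deg[i] + 1) * (deg[j] + 1)) ** gamma for i, j in remaining])
        idx = rng.choice(len(remaining), p=w / w.sum())
        i, j = remaining.pop(int(idx))
        chosen.append((i, j))
        deg[i] += 1
        deg[j] += 1
    return chosen


def simulate_score_network(spec: SimSpec) -> tuple[
        SimilarityTable, dict[str, str], list[tuple[str, str]]]:
    """Generate a synthetic EB-score table with families and held-out queries.

    Returns ``(table, members, queries)``: the full symmetric score
    table over every sequence (training members AND queries, so
    query-query scores exist for incremental learning), a map from
    training sequence id to family label, and the held-out
    ``(query_id, true_label)`` list.
    """
    rng = np.random.default_rng(spec.seed)
    table = SimilarityTable()
    fam_ids: dict[str, list[str]] = {}
    for f in range(spec.n_families):
        label = f"fam{f:03d}"
        ids = [f"{label}_s{m:03d}" for m in range(spec.family_size)]
        fam_ids[label] = ids
        for i, j in _preferential_edges(spec.family_size, spec.edge_keep_frac,
                                        spec.hub_gamma, rng):
            table.set(ids[i], ids[j], float(rng.lognormal(spec.mu_in, spec.sigma)))
    labels = sorted(fam_ids)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ids_a, ids_b = fam_ids[labels[a]], fam_ids[labels[b]]
            mask = rng.random((len(ids_a), len(ids_b))) < spec.cross_frac
            weights = rng.lognormal(spec.mu_out, spec.sigma, mask.shape)
            for i, j in zip(*np.nonzero(mask)):
                table.set(ids_a[i], ids_b[j], float(weights[i, j]))
    members: dict[str, str] = {}
    queries: list[tuple[str, str]] = []
    n_hold = max(1, round(spec.holdout_frac * spec.family_size))
    for label in labels:
        ids = fam_ids[label]
        held = rng.choice(len(ids), size=n_hold, replace=False)
        held_set = {int(h) for h in held}
        for m, sid in enumerate(ids):
            if m in held_set:
                queries.append((sid, label))
            else:
                members[sid] = label
    return table, members, queries


def simulate_sequences(spec: SimSpec, length: int = 200, mutation_rate: float = 0.1
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """Sequence-level families: one random ancestor per family, members
    mutated from it by i.i.d. per-site substitutions.

    Returns ``(sequences, families)``: id -> protein string and
    id -> family label.  No indels or rate heterogeneity — just enough
    divergence structure for the alignment route to separate families.
    """
    if not (0 < mutation_rate < 0.5):
        raise ValueError("mutation_rate must be in (0, 0.5)")
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    families: dict[str, str] = {}
    for f in range(spec.n_families):
        label = f"fam{f:03d}"
        ancestor = rng.choice(_AA, size=length)
        for m in range(spec.family_size):
            seq = ancestor.copy()
            hit = rng.random(length) < mutation_rate
            seq[hit] = rng.choice(_AA, size=int(hit.sum()))
            sid = f"{label}_s{m:03d}"
            sequences[sid] = "".join(seq)
            families[sid] = label
    return sequences, families


# ---------------------------------------------------------------------------
# Worked-example fixtures (unit edge weights)

def _unit_graph(label: str, vertices: list[str], edges: list[tuple[str, str]]) -> FamilyGraph:
    table = SimilarityTable()
    for a, b in edges:
        table.set(a, b, 1.0)
    return build_family_graph(label, vertices, table)


def fixture_clustered_hub() -> FamilyGraph:
    """Five-vertex example for AC and RC.

    Vertex c is a hub joined to a, b, d, e; a-b and d-e close two
    triangles.  At any threshold <= 1: AC = 13/15 (c contributes 1/3,
    the others 1 each) and phi(1) = 3/5.
    """
    return _unit_graph("demo_ac_rc", list("abcde"),
                       [("c", "a"), ("c", "b"), ("c", "d"), ("c", "e"),
                        ("a", "b"), ("d", "e")])


def fixture_star_vs_triangle() -> tuple[FamilyGraph, QueryAttachment]:
    """Seven-vertex example separating triangles from star motifs.

    Vertex a is a power-3 star centre (edges to x1, x2, x3) and only b-c
    interact among a, b, c, d.  The query q attaches to a, b, c and d:
    exactly one new triangle (q-b-c) forms, and a's star power rises
    from 3 to 4.  This is the minimal graph consistent with those facts;
    the unstated remainder is fixed here as "no further edges".
    """
    graph = _unit_graph("demo_sm_tr", ["a", "b", "c", "d", "x1", "x2", "x3"],
                        [("b", "c"), ("a", "x1"), ("a", "x2"), ("a", "x3")])
    vec = np.array([1.0 if v in {"a", "b", "c", "d"} else 0.0 for v in graph.vertices])
    return graph, QueryAttachment("q", vec)


def fixture_pyramid_demo() -> tuple[TrainedModel, dict[str, dict[str, QueryAttachment]]]:
    """Three-family model and five queries tracing the pyramid search.

    Each family is a complete 4-vertex graph with edge weight 30 and the
    AC ladder is (10, 20, 30), so a query attached to every member of a
    family at weight w first qualifies at the highest level <= w (the
    augmented view stays complete there, so the clustering delta is 0,
    which clears the secondary threshold T_AC = 0).  The five queries:

    q1  weight 20 to all of c2 and c3 -> candidates {c2, c3} at t* = 20
    q2  weight 30 to all of c1        -> {c1} at the top level
    q3  no interaction anywhere       -> empty set
    q4  weight 10 to all of c3        -> {c3} at the bottom level
    q5  weight 30 to all of c2 and c3 -> {c2, c3} at the top level
    """
    table = SimilarityTable()
    fams: dict[str, FamilyGraph] = {}
    for c in ("c1", "c2", "c3"):
        ids = [f"{c}_m{i}" for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                table.set(ids[i], ids[j], 30.0)
        fams[c] = build_family_graph(c, ids, table)
    ladder = (10.0, 20.0, 30.0)
    config = PyramidConfig(
        global_ladder=ladder,
        ladders={kind: ladder for kind in FeatureKind},
        t_ac=0.0, t_rc=0.0, p=2, r_low=1, r_high=2, k=3,
    )
    model = TrainedModel(fams, config, {"fixture": "pyramid_demo"})

    def _attach(qid: str, weight_by_family: dict[str, float]
                ) -> dict[str, QueryAttachment]:
        return {c: QueryAttachment(qid, np.full(4, weight_by_family.get(c, 0.0)))
                for c in fams}

    queries = {
        "q1": _attach("q1", {"c2": 20.0, "c3": 20.0}),
        "q2": _attach("q2", {"c1": 30.0}),
        "q3": _attach("q3", {}),
        "q4": _attach("q4", {"c3": 10.0}),
        "q5": _attach("q5", {"c2": 30.0, "c3": 30.0}),
    }
    return model, queries
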