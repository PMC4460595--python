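"""Hierarchical graph-pyramid classifier.

Training is instance-based: the model is just one weighted similarity
graph per family plus a threshold configuration.  Classification of a
query proceeds down a funnel of candidate sets:

1.  AC — a pyramid search over ALL families: starting from the highest
    threshold, find the first (i.e. largest) level t* at which the query
    interacts with at least one family and changes its average
    clustering by at least the secondary threshold T_AC.  Interaction at
    a high level is a strong (global) match.
2.  RC — the same search restricted to the AC candidates, using the
    rich-club coefficient with degree cut r (r switches from ``r_low``
    to ``r_high`` at the ladder midpoint).
3.  SM / TR — the k families of the RC candidates whose star-motif and
    triangle counts grow most (only strictly positive growth votes).
4.  GE — the k families of SM u TR with the largest graph-energy gain,
    evaluated at the BOTTOM of the energy ladder, where the views are
    dense enough for the spectrum to be informative.  The classifier
    defaults to the weighted-adjacency energy: on dense views the binary
    spectrum saturates (the gain stops growing with the number of query
    edges), whereas the weighted gain keeps tracking interaction
    strength.

The query's label is the mode of the pooled multiset of all five
candidate sets.  Ties are resolved by re-voting SM/TR with k = 1, then
by the single largest graph-energy gain; if no unique winner remains the
result is NO_DECISION — surfaced, never guessed.

Each decided query can be folded back into its predicted family's graph
(incremental learning), which enlarges the model without retraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .family_graph import (
    FamilyGraph,
    LabelMultiset,
    QueryAttachment,
    attach_query,
    attachment_from_table,
    mode_labels,
    multiset_sum,
)
from .gsf import FeatureKind, feature_delta
from .similarity import SimilarityTable

__all__ = [
    "NO_DECISION",
    "CandidateSet",
    "ClassificationResult",
    "PyramidConfig",
    "TrainedModel",
    "build_thresholds",
    "classify",
    "classify_all",
    "incremental_update",
    "k_max_candidates",
    "majority_classify",
    "max_eb_classify",
    "pyramid_search",
    "load_model",
    "save_model",
]

#: Sentinel prediction for an undecidable query (counted as "nd", never "wd").
NO_DECISION = None

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PyramidConfig:
    """Threshold ladders and voting parameters.

    ``global_ladder`` is an ascending list of edge-weight cutoffs
    (uniform quantization of (0, max EB-score]); each feature works on a
    contiguous slice of it.  ``r_low``/``r_high`` are the rich-club
    degree cuts below/above the ladder midpoint, ``p`` the star power,
    ``k`` the k-max fan-in of the SM/TR/GE votes, ``t_ac``/``t_rc`` the
    secondary thresholds on the feature deltas.
    """

    global_ladder: tuple[float, ...]
    ladders: Mapping[FeatureKind, tuple[float, ...]]
    t_ac: float = 0.0
    t_rc: float = 0.0
    p: int = 2
    r_low: int = 3
    r_high: int = 5
    k: int = 3
    weighted_ge: bool = True

    def __post_init__(self) -> None:
        if not self.global_ladder:
            raise ValueError("global ladder is empty")
        if any(b <= a for a, b in zip(self.global_ladder, self.global_ladder[1:])):
            raise ValueError("global ladder must be strictly ascending")
        for kind, ladder in self.ladders.items():
            if not ladder:
                raise ValueError(f"empty ladder for {kind}")
            if any(b <= a for a, b in zip(ladder, ladder[1:])):
                raise ValueError(f"ladder for {kind} must be strictly ascending")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p < 1:
            raise ValueError("star power p must be >= 1")

    @property
    def n_levels(self) -> int:
        return len(self.global_ladder)

    def level_index(self, t: float) -> int:
        """1-based index of threshold ``t`` on the global ladder."""
        for i, level in enumerate(self.global_ladder, start=1):
            if np.isclose(level, t):
                return i
        raise ValueError(f"{t} is not a global ladder level")

    def r_at(self, t: float) -> int:
        """Rich-club degree cut at level ``t``: r_high above the ladder
        midpoint, r_low at or below it."""
        return self.r_high if self.level_index(t) > self.n_levels / 2 else self.r_low


def _default_slices(n: int) -> dict[FeatureKind, tuple[int, int]]:
    """1-based inclusive (lo, hi) ladder slices per feature.

    AC/RC take the upper half (they are precise at high thresholds),
    SM/TR a middle band, GE the lowest levels where the views are dense.
    For n = 10: AC/RC 6-10, SM/TR 3-7, GE 1-2.
    """
    ac_lo = n // 2 + 1
    ge_hi = max(1, round(0.2 * n))
    sm_lo = min(ge_hi + 1, n)
    sm_hi = max(sm_lo, round(0.7 * n), n // 2)  # band abuts the AC slice
    return {
        FeatureKind.AC: (ac_lo, n),
        FeatureKind.RC: (ac_lo, n),
        FeatureKind.SM: (sm_lo, sm_hi),
        FeatureKind.TR: (sm_lo, sm_hi),
        FeatureKind.GE: (1, ge_hi),
    }


def build_thresholds(graphs: Iterable[FamilyGraph], n_levels: int = 10,
                     slices: Mapping[FeatureKind, tuple[int, int]] | None = None,
                     **config_kwargs) -> PyramidConfig:
    """Quantize the training edge-weight range into a threshold pyramid.

    The global ladder is ``n_levels`` uniformly spaced values over
    (0, w_max], w_max the largest edge weight over all training graphs;
    per-feature ladders are contiguous slices of it (1-based inclusive
    ``slices``, defaulting to the split described in the module docs).
    """
    if n_levels < 2:
        raise ValueError("need at least 2 pyramid levels")
    w_max = max((g.max_weight() for g in graphs), default=0.0)
    if w_max <= 0:
        raise ValueError("all training edge weights are zero: no pyramid possible")
    ladder = tuple(w_max * i / n_levels for i in range(1, n_levels + 1))
    slices = dict(slices) if slices is not None else _default_slices(n_levels)
    ladders = {}
    for kind in FeatureKind:
        lo, hi = slices[kind]
        if not (1 <= lo <= hi <= n_levels):
            raise ValueError(f"bad ladder slice for {kind}: ({lo}, {hi})")
        ladders[kind] = ladder[lo - 1:hi]
    return PyramidConfig(global_ladder=ladder, ladders=ladders, **config_kwargs)


@dataclass(frozen=True)
class TrainedModel:
    """Per-family similarity graphs plus the pyramid configuration."""

    families: Mapping[str, FamilyGraph]
    config: PyramidConfig
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("model has no families")
        for label, graph in self.families.items():
            if graph.label != label:
                raise ValueError(f"family key {label!r} != graph label {graph.label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))

    def attachments_for(self, query_id: str, table: SimilarityTable
                        ) -> dict[str, QueryAttachment]:
        """Look up the query's EB-scores against every family."""
        return {label: attachment_from_table(graph, query_id, table)
                for label, graph in self.families.items()}


def train(members_by_family: Mapping[str, Sequence[str]], table: SimilarityTable,
          n_levels: int = 10, **config_kwargs) -> TrainedModel:
    """Build one graph per family and quantize the pyramid thresholds."""
    from .family_graph import build_family_graph

    families = {label: build_family_graph(label, list(members), table)
                for label, members in sorted(members_by_family.items())}
    config = build_thresholds(families.values(), n_levels, **config_kwargs)
    provenance = {
        "n_families": len(families),
        "n_sequences": sum(g.n_vertices for g in families.values()),
        "format_version": MODEL_FORMAT_VERSION,
    }
    return TrainedModel(families, config, provenance)


@dataclass(frozen=True)
class CandidateSet:
    """Families shortlisted by one feature, and the level that found them."""

    labels: frozenset
    t_star: float

    def sorted_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels))


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    predicted: str | None
    candidates: Mapping[str, CandidateSet]
    votes: LabelMultiset
    tie_path: tuple[str, ...]
    feature_evaluations: int


class _EvalCounter:
    """Counts (feature, class, level) delta evaluations."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0


def _interacts(attachment: QueryAttachment, t: float) -> bool:
    v = attachment.eb_to_member
    return bool(np.any((v >= t) & (v > 0)))


def _delta(config: PyramidConfig, kind: FeatureKind, graph: FamilyGraph,
           attachment: QueryAttachment, t: float, counter: _EvalCounter) -> float:
    counter.count += 1
    return feature_delta(kind, graph, attachment, t,
                         r=config.r_at(t) if kind is FeatureKind.RC else 0,
                         p=config.p, weighted_ge=config.weighted_ge)


def pyramid_search(families: Mapping[str, FamilyGraph],
                   attachments: Mapping[str, QueryAttachment],
                   classes: Iterable[str], kind: FeatureKind,
                   ladder: Sequence[float], secondary: float,
                   config: PyramidConfig,
                   counter: _EvalCounter | None = None) -> CandidateSet:
    """Descend the ladder and collect classes at the first qualifying level.

    A class qualifies at level t when the query interacts with it there
    (at least one attachment weight survives t) and the feature delta
    clears the secondary threshold, ``delta - secondary >= 0`` (Heaviside
    boundary).  The scan stops at the first (highest) level with any
    qualifier; t* is that level.  With no qualifier anywhere the set is
    empty and t* is the ladder minimum.
    """
    counter = counter if counter is not None else _EvalCounter()
    classes = sorted(classes)
    unknown = [c for c in classes if c not in families]
    if unknown:
        raise KeyError(f"unknown class labels: {unknown}")
    for t in reversed(ladder):
        found = set()
        for c in classes:
            if not _interacts(attachments[c], t):
                continue
            if _delta(config, kind, families[c], attachments[c], t, counter) - secondary >= 0:
                found.add(c)
        if found:
            return CandidateSet(frozenset(found), float(t))
    return CandidateSet(frozenset(), float(ladder[0]))


def k_max_candidates(families: Mapping[str, FamilyGraph],
                     attachments: Mapping[str, QueryAttachment],
                     classes: Iterable[str], kind: FeatureKind,
                     t_star: float, k: int, config: PyramidConfig,
                     counter: _EvalCounter | None = None) -> CandidateSet:
    """The (up to) k classes with the largest strictly positive delta at
    ``t_star``; ties broken by ascending label order."""
    counter = counter if counter is not None else _EvalCounter()
    deltas = {c: _delta(config, kind, families[c], attachments[c], t_star, counter)
              for c in sorted(classes)}
    ranked = sorted((c for c, d in deltas.items() if d > 0),
                    key=lambda c: (-deltas[c], c))
    return CandidateSet(frozenset(ranked[:k]), float(t_star))


def _k_max_search(families, attachments, classes, kind, ladder, k, config, counter
                  ) -> CandidateSet:
    """Descend ``ladder``; at the first level where any class shows positive
    delta, return the k-max set there."""
    classes = sorted(classes)
    for t in reversed(ladder):
        active = [c for c in classes if _interacts(attachments[c], t)]
        if not active:
            continue
        deltas = {c: _delta(config, kind, families[c], attachments[c], t, counter)
                  for c in active}
        ranked = sorted((c for c, d in deltas.items() if d > 0),
                        key=lambda c: (-deltas[c], c))
        if ranked:
            return CandidateSet(frozenset(ranked[:k]), float(t))
    return CandidateSet(frozenset(), float(ladder[0]))


def _search_argmax(families, attachments, classes, kind, ladder, secondary,
                   config, counter) -> CandidateSet:
    """Like :func:`pyramid_search`, but nominate only the single class with
    the largest qualifying delta at t* (ties by ascending label)."""
    classes = sorted(classes)
    for t in reversed(ladder):
        deltas = {}
        for c in classes:
            if not _interacts(attachments[c], t):
                continue
            d = _delta(config, kind, families[c], attachments[c], t, counter)
            if d - secondary >= 0:
                deltas[c] = d
        if deltas:
            winner = min(deltas, key=lambda c: (-deltas[c], c))
            return CandidateSet(frozenset({winner}), float(t))
    return CandidateSet(frozenset(), float(ladder[0]))


def _argmax_ge(families, attachments, classes, t, config, counter) -> str | None:
    """Single class with the largest strictly positive graph-energy gain;
    ties broken by ascending label; None when no gain anywhere."""
    best, best_delta = None, 0.0
    for c in sorted(classes):
        d = _delta(config, FeatureKind.GE, families[c], attachments[c], t, counter)
        if d > best_delta:
            best, best_delta = c, d
    return best


def classify(model: TrainedModel,
             attachments: Mapping[str, QueryAttachment],
             query_id: str | None = None) -> ClassificationResult:
    """Hierarchical voting over the five graph features (see module docs).

    ``attachments`` must cover every family of the model.  The result
    records the full vote trail: per-feature candidate sets with their
    t* levels, the pooled vote multiset, which tie-resolution steps
    fired, and the number of feature evaluations spent.
    """
    missing = set(model.families) - set(attachments)
    if missing:
        raise KeyError(f"missing attachments for families: {sorted(missing)}")
    if query_id is None:
        query_id = next(iter(attachments.values())).query_id
    cfg = model.config
    fams = model.families
    counter = _EvalCounter()
    ge_t = cfg.ladders[FeatureKind.GE][0]

    c_ac = pyramid_search(fams, attachments, fams.keys(), FeatureKind.AC,
                          cfg.ladders[FeatureKind.AC], cfg.t_ac, cfg, counter)
    candidates: dict[str, CandidateSet] = {"AC": c_ac}
    tie_path: list[str] = []

    if not c_ac.labels:
        # The query interacts with nothing at any AC level; only the
        # low-threshold energy signal is left to consult.
        winner = _argmax_ge(fams, attachments, fams.keys(), ge_t, cfg, counter)
        tie_path.append("ac_empty_ge_only")
        empty = CandidateSet(frozenset(), c_ac.t_star)
        ge_set = CandidateSet(frozenset({winner} if winner else ()), float(ge_t))
        candidates.update({"RC": empty, "SM": empty, "TR": empty, "GE": ge_set})
        votes = LabelMultiset([winner] if winner else [])
        return ClassificationResult(query_id, winner if winner else NO_DECISION,
                                    candidates, votes, tuple(tie_path), counter.count)

    c_rc = pyramid_search(fams, attachments, c_ac.labels, FeatureKind.RC,
                          cfg.ladders[FeatureKind.RC], cfg.t_rc, cfg, counter)
    candidates["RC"] = c_rc
    c_sm = _k_max_search(fams, attachments, c_rc.labels, FeatureKind.SM,
                         cfg.ladders[FeatureKind.SM], cfg.k, cfg, counter)
    c_tr = _k_max_search(fams, attachments, c_rc.labels, FeatureKind.TR,
                         cfg.ladders[FeatureKind.TR], cfg.k, cfg, counter)
    candidates["SM"], candidates["TR"] = c_sm, c_tr
    ge_domain = c_sm.labels | c_tr.labels
    c_ge = k_max_candidates(fams, attachments, ge_domain, FeatureKind.GE,
                            ge_t, cfg.k, cfg, counter) if ge_domain else \
        CandidateSet(frozenset(), float(ge_t))
    candidates["GE"] = c_ge

    votes = LabelMultiset()
    for cs in (c_ac, c_rc, c_sm, c_tr, c_ge):
        votes = multiset_sum(votes, LabelMultiset(cs.sorted_labels()))
    if len(votes) == 0:
        return ClassificationResult(query_id, NO_DECISION, candidates, votes,
                                    ("no_votes",), counter.count)

    psi = mode_labels(votes)
    if len(psi) == 1:
        return ClassificationResult(query_id, next(iter(psi)), candidates, votes,
                                    tuple(tie_path), counter.count)

    # Indecisive: re-vote SM and TR with k = 1 at their found levels.
    tie_path.append("k1_revote")
    c_sm1 = k_max_candidates(fams, attachments, c_rc.labels, FeatureKind.SM,
                             c_sm.t_star, 1, cfg, counter)
    c_tr1 = k_max_candidates(fams, attachments, c_rc.labels, FeatureKind.TR,
                             c_tr.t_star, 1, cfg, counter)
    revote = LabelMultiset()
    for cs in (c_sm1, c_tr1, c_ge):
        revote = multiset_sum(revote, LabelMultiset(cs.sorted_labels()))
    if len(revote) > 0:
        psi2 = mode_labels(revote)
        if len(psi2) == 1:
            return ClassificationResult(query_id, next(iter(psi2)), candidates, votes,
                                        tuple(tie_path), counter.count)

    # Persistent tie: the threshold has hit bottom; rely on graph energy.
    tie_path.append("ge_fallback")
    domain = ge_domain if ge_domain else c_rc.labels
    winner = _argmax_ge(fams, attachments, domain, ge_t, cfg, counter) if domain else None
    return ClassificationResult(query_id, winner if winner else NO_DECISION,
                                candidates, votes, tuple(tie_path), counter.count)


def majority_classify(model: TrainedModel,
                      attachments: Mapping[str, QueryAttachment],
                      query_id: str | None = None) -> ClassificationResult:
    """Flat majority-voting baseline (no hierarchy).

    Every feature independently scans ALL families down its own ladder
    and nominates the class with the largest qualifying delta at its
    own t*; the prediction is the mode of the five votes, ties giving
    NO_DECISION.  Costs more feature evaluations than the funnel because
    nothing shrinks the search space.
    """
    missing = set(model.families) - set(attachments)
    if missing:
        raise KeyError(f"missing attachments for families: {sorted(missing)}")
    if query_id is None:
        query_id = next(iter(attachments.values())).query_id
    cfg = model.config
    fams = model.families
    counter = _EvalCounter()
    candidates: dict[str, CandidateSet] = {}
    ballot: list[str] = []

    for kind in FeatureKind:
        ladder = cfg.ladders[kind]
        if kind is FeatureKind.GE:
            cs = k_max_candidates(fams, attachments, fams.keys(), kind,
                                  ladder[0], 1, cfg, counter)
        elif kind in (FeatureKind.AC, FeatureKind.RC):
            secondary = cfg.t_ac if kind is FeatureKind.AC else cfg.t_rc
            cs = _search_argmax(fams, attachments, fams.keys(), kind, ladder,
                                secondary, cfg, counter)
        else:
            cs = _k_max_search(fams, attachments, fams.keys(), kind, ladder,
                               1, cfg, counter)
        candidates[kind.value] = cs
        ballot.extend(cs.sorted_labels())

    votes = LabelMultiset(ballot)
    if len(votes) == 0:
        return ClassificationResult(query_id, NO_DECISION, candidates, votes,
                                    ("no_votes",), counter.count)
    psi = mode_labels(votes)
    predicted = next(iter(psi)) if len(psi) == 1 else NO_DECISION
    path = () if len(psi) == 1 else ("majority_tie",)
    return ClassificationResult(query_id, predicted, candidates, votes,
                                path, counter.count)


def max_eb_classify(model: TrainedModel,
                    attachments: Mapping[str, QueryAttachment],
                    query_id: str | None = None) -> ClassificationResult:
    """Global-feature baseline: the family holding the single strongest
    EB-score match wins (the classical best-BLAST-hit strategy)."""
    if query_id is None:
        query_id = next(iter(attachments.values())).query_id
    best, best_eb = None, 0.0
    for label in sorted(model.families):
        eb = float(attachments[label].eb_to_member.max(initial=0.0))
        if eb > best_eb:
            best, best_eb = label, eb
    votes = LabelMultiset([best] if best else [])
    cs = CandidateSet(frozenset({best} if best else ()), 0.0)
    return ClassificationResult(query_id, best if best else NO_DECISION,
                                {"MAX_EB": cs}, votes, (), len(model.families))


def incremental_update(model: TrainedModel, query_id: str, predicted: str,
                       attachments: Mapping[str, QueryAttachment]) -> TrainedModel:
    """Fold a decided query into its predicted family's graph.

    Returns a new model in which only the predicted family changed; the
    updated graph is exactly what a from-scratch rebuild on the enlarged
    member list would produce.
    """
    if predicted is NO_DECISION:
        raise ValueError("cannot update the model from a NO_DECISION result")
    if predicted not in model.families:
        raise KeyError(f"unknown family {predicted!r}")
    families = dict(model.families)
    families[predicted] = attach_query(families[predicted], attachments[predicted])
    return replace(model, families=families)


def classify_all(model: TrainedModel, query_ids: Sequence[str], table: SimilarityTable,
                 *, update: bool = False, update_only_confident: bool = False
                 ) -> tuple[list[ClassificationResult], TrainedModel]:
    """Classify queries in order, optionally learning incrementally.

    With ``update`` every decided query is added back to its predicted
    family before the next query is processed;
    ``update_only_confident`` additionally requires a tie-free vote.
    Returns the results and the (possibly enlarged) final model.
    """
    results = []
    for qid in query_ids:
        attachments = model.attachments_for(qid, table)
        res = classify(model, attachments, qid)
        results.append(res)
        if res.predicted is not NO_DECISION and (update or update_only_confident):
            if update_only_confident and res.tie_path:
                continue
            model = incremental_update(model, qid, res.predicted, attachments)
    return results, model


# ---------------------------------------------------------------------------
# Model persistence: a directory with a JSON manifest and one dense TSV
# weight matrix per family (header row and column of sequence ids).

def _config_to_json(cfg: PyramidConfig) -> dict:
    return {
        "global_ladder": list(cfg.global_ladder),
        "ladders": {k.value: list(v) for k, v in cfg.ladders.items()},
        "t_ac": cfg.t_ac, "t_rc": cfg.t_rc, "p": cfg.p,
        "r_low": cfg.r_low, "r_high": cfg.r_high, "k": cfg.k,
        "weighted_ge": cfg.weighted_ge,
    }


def _config_from_json(obj: dict) -> PyramidConfig:
    return PyramidConfig(
        global_ladder=tuple(obj["global_ladder"]),
        ladders={FeatureKind(k): tuple(v) for k, v in obj["ladders"].items()},
        t_ac=obj["t_ac"], t_rc=obj["t_rc"], p=obj["p"],
        r_low=obj["r_low"], r_high=obj["r_high"], k=obj["k"],
        weighted_ge=obj["weighted_ge"],
    )


def save_model(model: TrainedModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "families": {label: {"file": f"family_{i}.tsv",
                             "vertices": list(g.vertices)}
                     for i, (label, g) in enumerate(sorted(model.families.items()))},
        "config": _config_to_json(model.config),
        "provenance": dict(model.provenance),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for i, (label, g) in enumerate(sorted(model.families.items())):
        with open(directory / f"family_{i}.tsv", "w") as fh:
            fh.write("id\t" + "\t".join(g.vertices) + "\n")
            for vid, row in zip(g.vertices, g.weights):
                fh.write(vid + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def load_model(directory) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version "
                         f"{manifest.get('format_version')!r}")
    families = {}
    for label, info in manifest["families"].items():
        lines = (directory / info["file"]).read_text().splitlines()
        header = lines[0].split("\t")[1:]
        if header != info["vertices"]:
            raise ValueError(f"vertex list mismatch in family {label!r}")
        w = np.array([[float(x) for x in line.split("\t")[1:]] for line in lines[1:]])
        families[label] = FamilyGraph(label, tuple(header), w)
    return TrainedModel(families, _config_from_json(manifest["config"]),
                        manifest.get("provenance", {}))
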