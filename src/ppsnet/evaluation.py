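"""Evaluation metrics: cd/wd/nd accounting, precision, ROC sweeps,
and the evaluation-count efficiency comparison.

Every query decision is one of three outcomes: a correct decision (cd),
a wrong decision (wd), or no decision (nd — the voter could not name a
unique family).  The headline metric is precision = cd / (cd + wd);
no-decisions are reported separately and never counted as wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

from .pyramid import (
    NO_DECISION,
    ClassificationResult,
    TrainedModel,
    classify,
    majority_classify,
)
from .similarity import SimilarityTable

__all__ = [
    "EvalReport",
    "compare_efficiency",
    "evaluate",
    "roc_sweep",
    "write_predictions_tsv",
]


@dataclass(frozen=True)
class EvalReport:
    """Tally of classification outcomes against ground truth."""

    cd: int
    wd: int
    nd: int
    per_family: Mapping[str, tuple[int, int, int]]
    feature_evaluations: int

    @property
    def n_queries(self) -> int:
        return self.cd + self.wd + self.nd

    @property
    def precision(self) -> float | None:
        """cd / (cd + wd); None (not 0) when nothing was decided."""
        decided = self.cd + self.wd
        return self.cd / decided if decided else None

    @property
    def accuracy(self) -> float | None:
        """cd / all queries — counts nd against the classifier."""
        return self.cd / self.n_queries if self.n_queries else None


def evaluate(results: Iterable[ClassificationResult],
             truth: Mapping[str, str]) -> EvalReport:
    """Tally cd/wd/nd per family; every query must carry a truth label."""
    cd = wd = nd = 0
    evals = 0
    per_family: dict[str, list[int]] = {}
    for res in results:
        if res.query_id not in truth:
            raise KeyError(f"no truth label for query {res.query_id!r}")
        true = truth[res.query_id]
        row = per_family.setdefault(true, [0, 0, 0])
        evals += res.feature_evaluations
        if res.predicted is NO_DECISION:
            nd += 1
            row[2] += 1
        elif res.predicted == true:
            cd += 1
            row[0] += 1
        else:
            wd += 1
            row[1] += 1
    return EvalReport(cd, wd, nd,
                      {k: tuple(v) for k, v in sorted(per_family.items())}, evals)


def roc_sweep(model: TrainedModel, query_ids: Sequence[str], table: SimilarityTable,
              truth: Mapping[str, str],
              grid: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """One classification pass per (T_AC, T_RC) grid point.

    Rates are micro-averaged one-vs-rest over families: with M families
    and n queries, a correct decision is one true positive and a wrong
    decision one false positive among the n*(M-1) negative
    (query, family) pairs.  Points are returned sorted by FP rate.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    m = len(model.families)
    points = []
    for t_ac, t_rc in grid:
        swept = replace(model, config=replace(model.config, t_ac=t_ac, t_rc=t_rc))
        results = [classify(swept, swept.attachments_for(q, table), q)
                   for q in query_ids]
        report = evaluate(results, truth)
        tpr = report.cd / report.n_queries
        fpr = report.wd / (report.n_queries * max(m - 1, 1))
        points.append((fpr, tpr))
    return sorted(points)


def compare_efficiency(model: TrainedModel, query_ids: Sequence[str],
                       table: SimilarityTable) -> dict[str, int]:
    """Total (feature, class, level) evaluation counts per voting scheme.

    A deterministic, hardware-independent proxy for testing time: the
    hierarchical funnel shrinks the candidate pool between features,
    flat majority voting scans every family with every feature.
    """
    counts = {"hierarchical": 0, "majority": 0}
    for qid in query_ids:
        attachments = model.attachments_for(qid, table)
        counts["hierarchical"] += classify(model, attachments, qid).feature_evaluations
        counts["majority"] += majority_classify(model, attachments, qid).feature_evaluations
    return counts


def write_predictions_tsv(stream: TextIO, results: Iterable[ClassificationResult],
                          truth: Mapping[str, str] | None = None) -> None:
    """Write one row per query: prediction, cd/wd/nd status (if truth is
    given), per-feature t* levels and the vote multiset."""
    stream.write("query_id\tpredicted\tstatus\t" +
                 "\t".join(f"t_star_{k}" for k in ("AC", "RC", "SM", "TR", "GE")) +
                 "\tvotes\n")
    for res in results:
        if truth is None:
            status = "-"
        elif res.predicted is NO_DECISION:
            status = "nd"
        else:
            status = "cd" if res.predicted == truth[res.query_id] else "wd"
        t_stars = "\t".join(
            f"{res.candidates[k].t_star:g}" if k in res.candidates else "-"
            for k in ("AC", "RC", "SM", "TR", "GE"))
        votes = ",".join(f"{label}:{c}" for label, c in sorted(res.votes.counts.items()))
        stream.write(f"{res.query_id}\t{res.predicted or 'ND'}\t{status}\t"
                     f"{t_stars}\t{votes or '-'}\n")
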