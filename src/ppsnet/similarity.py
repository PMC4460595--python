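"""Pairwise sequence similarity and the EB-score.

BLAST reports two statistics per hit: the E-value (expected number of
chance hits of at least this quality in the search space) and the
bit-score (a search-space-independent rescaling of the raw alignment
score).  The two carry slightly different information, so they are fused
into a single nonnegative similarity, the EB-score::

    eb       = -log(E-value) * bit-score
    EB-score = eb * H(eb)

where ``H`` is the Heaviside step with ``H(0) = 1``.  An E-value of 1 or
more therefore yields EB = 0 ("no detectable similarity"), which is also
the value reported for pairs that were never scored at all.

Scores may come from parsed BLAST tabular output, from a generic
four-column TSV, or from the built-in local aligner (:func:`align_pair`)
so that a FASTA file alone is enough to run the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "EVALUE_FLOOR",
    "AlignmentParams",
    "SimilarityHit",
    "SimilarityTable",
    "align_pair",
    "eb_score",
    "heaviside",
    "parse_blast_tabular",
    "parse_score_tsv",
    "read_fasta",
    "score_fasta",
    "symmetrize",
    "write_score_tsv",
]

#: E-values of exactly 0 (reported by BLAST on underflow) are clamped to
#: this floor before taking the log, keeping the EB-score finite while
#: preserving the ordering of every representable E-value above it.
EVALUE_FLOOR = 1e-180

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised for malformed tabular input; carries the offending line number."""


def heaviside(x: float) -> int:
    """Heaviside step function with the ``H(0) = 1`` convention.

    The boundary choice matters throughout: an edge whose weight exactly
    equals a pruning threshold survives.
    """
    if not math.isfinite(x):
        raise ValueError(f"heaviside requires a finite argument, got {x!r}")
    return 1 if x >= 0 else 0


def eb_score(evalue: float, bitscore: float, *, log_base: float = math.e) -> float:
    """Fuse an E-value and a bit-score into the nonnegative EB-score.

    ``eb = -log(evalue) * bitscore`` clamped to zero by the Heaviside
    step, so hits with E-value >= 1 (or negative ``eb``) score 0.

    Parameters
    ----------
    evalue:
        BLAST expectation value, >= 0.  Zero is clamped to
        :data:`EVALUE_FLOOR` before the logarithm.
    bitscore:
        Alignment bit-score.
    log_base:
        Base of the logarithm; natural log by default, the convention of
        E-value statistics.
    """
    if evalue < 0:
        raise ValueError(f"evalue must be nonnegative, got {evalue}")
    eb = -math.log(max(evalue, EVALUE_FLOOR), log_base) * bitscore
    return eb * heaviside(eb)


@dataclass(frozen=True)
class SimilarityHit:
    """One directed pairwise hit (query vs subject) with its statistics."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("sequence identifiers must be nonempty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be nonnegative, got {self.evalue}")


class SimilarityTable:
    """Symmetric map from unordered sequence-id pairs to EB-scores.

    Self-pairs are never stored; looking up an unknown pair returns 0,
    i.e. "no detectable similarity".
    """

    def __init__(self, entries: dict[frozenset, float] | None = None) -> None:
        self._entries: dict[frozenset, float] = {}
        if entries:
            for key, eb in entries.items():
                pair = frozenset(key)
                if len(pair) != 2:
                    raise ValueError(f"not an unordered pair of two ids: {key!r}")
                if eb < 0:
                    raise ValueError(f"EB-score must be nonnegative, got {eb}")
                self._entries[pair] = float(eb)

    def get(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 0.0
        return self._entries.get(frozenset((id_a, id_b)), 0.0)

    def set(self, id_a: str, id_b: str, eb: float) -> None:
        if id_a == id_b:
            raise ValueError(f"self-pair {id_a!r} cannot be stored")
        if eb < 0:
            raise ValueError(f"EB-score must be nonnegative, got {eb}")
        self._entries[frozenset((id_a, id_b))] = float(eb)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[tuple[str, str], float]]:
        for pair, eb in self._entries.items():
            a, b = sorted(pair)
            yield (a, b), eb

    def ids(self) -> set[str]:
        out: set[str] = set()
        for pair in self._entries:
            out.update(pair)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityTable):
            return NotImplemented
        return self._entries == other._entries


def parse_blast_tabular(stream: Iterable[str]) -> list[SimilarityHit]:
    """Parse BLAST tabular output (``-outfmt 6``, 12 tab-separated columns).

    Columns 1-2 are query/subject ids, column 11 the E-value, column 12
    the bit-score; ``#`` comment lines and blank lines are skipped.
    Multiple HSPs for a pair yield multiple hits; deduplication happens
    in :func:`symmetrize`.
    """
    hits: list[SimilarityHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise FormatError(
                f"line {lineno}: expected >= 12 tab-separated columns, got {len(cols)}"
            )
        try:
            evalue = float(cols[10])
            bitscore = float(cols[11])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparsable numeric field: {exc}") from exc
        try:
            hits.append(SimilarityHit(cols[0], cols[1], evalue, bitscore))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return hits


_SCORE_TSV_HEADER = ("id_a", "id_b", "evalue", "bitscore")


def parse_score_tsv(stream: Iterable[str]) -> list[SimilarityHit]:
    """Parse the generic pair-score TSV ``id_a  id_b  evalue  bitscore``."""
    hits: list[SimilarityHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if [c.strip() for c in cols[:4]] == list(_SCORE_TSV_HEADER):
            continue
        if len(cols) < 4:
            raise FormatError(f"line {lineno}: expected 4 columns, got {len(cols)}")
        try:
            hits.append(SimilarityHit(cols[0], cols[1], float(cols[2]), float(cols[3])))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return hits


def write_score_tsv(stream: TextIO, hits: Iterable[SimilarityHit]) -> None:
    stream.write("\t".join(_SCORE_TSV_HEADER) + "\n")
    for hit in hits:
        stream.write(f"{hit.query_id}\t{hit.subject_id}\t{hit.evalue:.6g}\t{hit.bitscore:.6g}\n")


def symmetrize(hits: Iterable[SimilarityHit], *, log_base: float = math.e) -> SimilarityTable:
    """Collapse directed hits into a symmetric EB-score table.

    The similarity graph is undirected, so each unordered pair gets one
    weight: the maximum EB-score over both search directions and over
    multiple HSPs — the strongest evidence wins.  Self-hits are dropped.
    """
    table = SimilarityTable()
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        eb = eb_score(hit.evalue, hit.bitscore, log_base=log_base)
        if eb > table.get(hit.query_id, hit.subject_id):
            table.set(hit.query_id, hit.subject_id, eb)
    return table


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the built-in local aligner.

    Defaults are the standard gapped protein-BLAST values (BLOSUM62,
    gap open 11 / extend 1, Karlin-Altschul lambda 0.267, kappa 0.041),
    so bit-scores and E-values come out on BLAST-comparable scales.
    ``search_space`` defaults to the product of the two sequence lengths.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_kappa: float = 0.041
    search_space: float | None = None

    def __post_init__(self) -> None:
        if self.karlin_lambda <= 0 or self.karlin_kappa <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")


def _validate_protein(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains invalid residues: {sorted(bad)}")
    return seq


def local_alignment_score(seq_a: str, seq_b: str, params: AlignmentParams) -> float:
    """Raw Smith–Waterman score with affine gaps under ``params``.

    A gap of length k costs ``gap_open + k * gap_extend``, the BLAST
    convention.
    """
    seq_a = _validate_protein(seq_a, "seq_a")
    seq_b = _validate_protein(seq_b, "seq_b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return float(aligner.score(seq_a, seq_b))


def align_pair(seq_a: str, seq_b: str, params: AlignmentParams | None = None,
               *, query_id: str = "query", subject_id: str = "subject") -> SimilarityHit:
    """Score a sequence pair with the built-in aligner.

    Computes the raw local-alignment score S, then
    ``bitscore = (lambda*S - ln kappa) / ln 2`` and
    ``evalue = search_space * 2**(-bitscore)``.  Deterministic; intended
    as a drop-in scorer when no external search tool output is on hand.
    """
    if params is None:
        params = AlignmentParams()
    raw = local_alignment_score(seq_a, seq_b, params)
    bitscore = (params.karlin_lambda * raw - math.log(params.karlin_kappa)) / math.log(2)
    space = params.search_space if params.search_space is not None else len(seq_a) * len(seq_b)
    evalue = space * 2.0 ** (-bitscore)
    return SimilarityHit(query_id, subject_id, evalue, bitscore)


def read_fasta(path) -> dict[str, str]:
    """Read a (wrapped or unwrapped) multi-record FASTA into id -> sequence."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def score_fasta(sequences: dict[str, str], params: AlignmentParams | None = None,
                *, ids_a: list[str] | None = None,
                ids_b: list[str] | None = None) -> SimilarityTable:
    """All-vs-all (or rectangular) EB-score table from raw sequences.

    ``ids_a``/``ids_b`` restrict the comparison to a rectangle, e.g.
    queries vs training members; by default every unordered pair is
    scored.
    """
    if params is None:
        params = AlignmentParams()
    ids_a = list(sequences) if ids_a is None else ids_a
    ids_b = list(sequences) if ids_b is None else ids_b
    table = SimilarityTable()
    seen: set[frozenset] = set()
    for a in ids_a:
        for b in ids_b:
            if a == b:
                continue
            pair = frozenset((a, b))
            if pair in seen:
                continue
            seen.add(pair)
            hit = align_pair(sequences[a], sequences[b], params, query_id=a, subject_id=b)
            eb = eb_score(hit.evalue, hit.bitscore)
            if eb > 0:
                table.set(a, b, eb)
    return table
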