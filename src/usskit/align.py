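"""Local protein alignment and per-query best-hit ranking.

Smith-Waterman local alignment under BLOSUM62 with affine gaps (open 11,
extend 1 — the conventional protein-search defaults), computed with
Biopython's PairwiseAligner. Identity and similarity percentages use the
full alignment length (columns including gaps) as denominator, matching how
alignment length is reported alongside identity in homology screen tables.

Ranking is by raw score; no E-value model is attached (hit tables ingested
from external tools keep their E-values for reporting only).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import HomologyHit, ProteinRecord

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

GAP = "-"


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal local alignment with its report statistics."""

    query_id: str
    subject_id: str
    score: float
    aligned_query: str
    aligned_subject: str
    pct_identity: float
    pct_similarity: float

    @property
    def aln_len(self) -> int:
        return len(self.aligned_query)

    def to_hit(self, query_len: int, subject_len: int) -> HomologyHit:
        return HomologyHit(
            query_id=self.query_id,
            subject_id=self.subject_id,
            pct_identity=self.pct_identity,
            pct_similarity=self.pct_similarity,
            aln_len=self.aln_len,
            query_len=query_len,
            subject_len=subject_len,
            score=self.score,
        )


@lru_cache(maxsize=8)
def _make_aligner(
    matrix: str, gap_open: int, gap_extend: int
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # First gap residue costs open+extend; each further residue costs extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _column_stats(
    aligned_q: str, aligned_s: str, matrix
) -> tuple[float, float]:
    """(pct_identity, pct_similarity) over alignment columns incl. gaps."""
    n = len(aligned_q)
    if n == 0:
        return 0.0, 0.0
    ident = 0
    similar = 0
    for a, b in zip(aligned_q, aligned_s):
        if a == GAP or b == GAP:
            continue
        if a == b:
            ident += 1
        if matrix[a, b] > 0:
            similar += 1
    return 100.0 * ident / n, 100.0 * similar / n


def local_score(
    query: str,
    subject: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal local alignment score only (no traceback)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    return float(
        _make_aligner(matrix, gap_open, gap_extend).score(query, subject)
    )


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult | None:
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns None ("no hit") when no positive-scoring local alignment exists.
    When several alignments are co-optimal one is chosen deterministically.
    """
    if query.length_aa < 1 or subject.length_aa < 1:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(query.residues, subject.residues))
    if score <= 0:
        return None
    alignment = aligner.align(query.residues, subject.residues)[0]
    aligned_q, aligned_s = str(alignment[0]), str(alignment[1])
    pid, psim = _column_stats(
        aligned_q, aligned_s, aligner.substitution_matrix
    )
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        pct_identity=pid,
        pct_similarity=psim,
    )


def best_hits(
    queries: list[ProteinRecord],
    subjects: list[ProteinRecord],
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> dict[str, list[AlignmentResult]]:
    """Per-query ranked hit lists over a subject set.

    Hits are sorted by score descending, ties broken by higher identity and
    then lexicographic subject id, so the ranking is deterministic. Queries
    with no positive-scoring alignment map to an empty list.
    """
    if not subjects:
        raise ValueError("subject set is empty")
    out: dict[str, list[AlignmentResult]] = {}
    for q in queries:
        hits = []
        for s in subjects:
            res = local_align(q, s, matrix, gap_open, gap_extend)
            if res is not None:
                hits.append(res)
        hits.sort(key=lambda r: (-r.score, -r.pct_identity, r.subject_id))
        out[q.id] = hits
    return out
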