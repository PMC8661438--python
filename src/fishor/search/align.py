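"""Protein local alignment and Karlin-Altschul e-value statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Parameters of the extreme-value statistics E = K*m*n*exp(-lam*S).

    Defaults are the published gapped BLOSUM62 (open 11 / extend 1) values,
    which reproduce tblastn-scale e-values without external binaries.
    """

    lam: float = 0.267
    K: float = 0.041


DEFAULT_KA = KarlinAltschulParams()


def evalue(raw_score: float, m: int, n: float, params: KarlinAltschulParams = DEFAULT_KA) -> float:
    """Expected number of chance local alignments scoring >= ``raw_score``.

    ``m`` is the query length (aa) and ``n`` the database length in
    aa-equivalents; no edge-length correction is applied.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions m, n must be positive")
    return params.K * m * n * math.exp(-params.lam * raw_score)


def bit_score(raw_score: float, params: KarlinAltschulParams = DEFAULT_KA) -> float:
    """Normalized score: (lam*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.K)) / math.log(2)


def min_raw_score(evalue_max: float, m: int, n: float,
                  params: KarlinAltschulParams = DEFAULT_KA) -> float:
    """Smallest raw score whose e-value is <= ``evalue_max``."""
    return (math.log(params.K * m * n) - math.log(evalue_max)) / params.lam


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def get_aligner(matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1,
                mode: str = "local") -> Align.PairwiseAligner:
    """Shared PairwiseAligner configured with BLAST-style gap costs.

    A gap of length k costs gap_open + k*gap_extend, matching the BLAST
    convention for "open 11 / extend 1".
    """
    key = (matrix, gap_open, gap_extend, mode)
    if key not in _ALIGNER_CACHE:
        try:
            sub = substitution_matrices.load(matrix)
        except FileNotFoundError as exc:
            raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = sub
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        aligner.mode = mode
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def local_align(query: str, subject: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1):
    """Optimal Smith-Waterman local alignment under affine gaps.

    Returns ``(raw_score, query_spans, subject_spans)`` where the spans are
    tuples of half-open intervals describing the aligned blocks. The score
    of an empty alignment is 0, so the returned score is always >= 0.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    aligner = get_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    score = alignments.score
    if score <= 0:
        return 0.0, (), ()
    aln = alignments[0]
    q_spans = tuple((int(a), int(b)) for a, b in aln.aligned[0])
    s_spans = tuple((int(a), int(b)) for a, b in aln.aligned[1])
    return float(score), q_spans, s_spans


def local_score(query: str, subject: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> float:
    """Score-only variant of :func:`local_align` (faster; no traceback)."""
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    score = get_aligner(matrix, gap_open, gap_extend).score(query, subject)
    return max(0.0, float(score))
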