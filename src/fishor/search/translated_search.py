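"""Seeded six-frame translated search of a genome with protein queries.

The engine mirrors the tblastn contract: every scaffold is translated in
all six frames, candidate windows are located by exact amino-acid k-mer
seeding, and each window is scored by Smith-Waterman under BLOSUM62 with
Karlin-Altschul e-values. Iterative masking recovers multiple
non-overlapping hits per frame. Coordinates are 0-based half-open on the
forward scaffold strand throughout; minus-strand hits are reported in
forward coordinates with ``strand == '-'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from fishor.search.align import (DEFAULT_KA, KarlinAltschulParams, bit_score,
                                 evalue, get_aligner, min_raw_score)
from fishor.search.translate import revcomp, translate

SEED_WORD = 5
_WINDOW_PAD = 20  # aa of slack around the seeded span


@dataclass
class SearchHit:
    """One translated-search high-scoring pair."""

    query_id: str
    scaffold_id: str
    start: int            # nt, forward strand, 0-based
    end: int              # nt, half-open
    strand: str           # '+' or '-'
    frame: int            # 0|1|2 on the searched strand
    raw_score: float
    bit: float
    evalue: float
    query_start: int      # aa, 0-based
    query_end: int        # aa, half-open
    identity: float       # fraction identical over aligned columns
    length: int           # aligned columns (aa)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def as_scaffolds(genome) -> list[tuple[str, str]]:
    """Normalize genome input to a list of (id, sequence) pairs.

    Accepts a SyntheticGenome-like object (``.scaffolds``), a mapping, an
    iterable of pairs, or a FASTA path.
    """
    if hasattr(genome, "scaffolds"):
        return list(genome.scaffolds)
    if isinstance(genome, dict):
        return list(genome.items())
    if isinstance(genome, (str, Path)):
        from Bio import SeqIO

        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(genome), "fasta")]
    return list(genome)


def _as_queries(queries) -> list[tuple[str, str]]:
    if isinstance(queries, dict):
        return list(queries.items())
    out = []
    for q in queries:
        if isinstance(q, tuple):
            out.append(q)
        elif hasattr(q, "id") and hasattr(q, "seq"):
            out.append((q.id, str(q.seq)))
        else:
            raise TypeError(f"cannot interpret query {q!r}")
    return out


def _kmer_index(protein: str, k: int = SEED_WORD) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(protein) - k + 1):
        word = protein[i : i + k]
        if "*" in word or "X" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _seed_windows(query: str, subject_index: dict[str, list[int]],
                  subject_len: int, k: int = SEED_WORD) -> list[tuple[int, int]]:
    """Candidate subject windows (aa coords) from shared k-mers.

    Each seed at query offset i / subject position p implies an alignment
    roughly on diagonal p - i; the window spans that diagonal's projection
    of the full query plus slack, and overlapping windows are merged.
    """
    qlen = len(query)
    starts: list[int] = []
    for i in range(qlen - k + 1):
        hits = subject_index.get(query[i : i + k])
        if hits:
            for p in hits:
                starts.append(p - i)
    if not starts:
        return []
    starts.sort()
    windows: list[list[int]] = []
    for d in starts:
        lo = max(0, d - _WINDOW_PAD)
        hi = min(subject_len, d + qlen + _WINDOW_PAD)
        if windows and lo <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    return [(a, b) for a, b in windows]


def _identity(query: str, subject: str, q_spans, s_spans) -> tuple[float, int]:
    matched = 0
    total = 0
    for (qa, qb), (sa, sb) in zip(q_spans, s_spans):
        for off in range(qb - qa):
            total += 1
            if query[qa + off] == subject[sa + off]:
                matched += 1
    # count gap columns into alignment length
    gap_cols = 0
    for idx in range(1, len(q_spans)):
        gap_cols += (q_spans[idx][0] - q_spans[idx - 1][1]) + (s_spans[idx][0] - s_spans[idx - 1][1])
    total_cols = total + gap_cols
    return (matched / total if total else 0.0), total_cols


def search_translated(queries, genome, evalue_max: float = 1e-10,
                      params: KarlinAltschulParams = DEFAULT_KA,
                      matrix: str = "BLOSUM62", gap_open: int = 11,
                      gap_extend: int = 1, max_hits_per_window: int = 8,
                      ) -> list[SearchHit]:
    """Six-frame translated search of every scaffold, both strands.

    Returns hits with e-value <= ``evalue_max`` sorted by
    (scaffold, start). The e-value search space is m = query length (aa),
    n = total genome length / 3 (aa-equivalents).
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    scaffolds = as_scaffolds(genome)
    qlist = _as_queries(queries)
    if not scaffolds or not qlist:
        return []
    total_nt = sum(len(seq) for _, seq in scaffolds)
    n_aa = max(total_nt / 3.0, 1.0)
    aligner = get_aligner(matrix, gap_open, gap_extend)
    hits: list[SearchHit] = []
    for scaf_id, scaf_seq in scaffolds:
        L = len(scaf_seq)
        for strand in ("+", "-"):
            seq = scaf_seq if strand == "+" else revcomp(scaf_seq)
            for frame in range(3):
                prot = translate(seq, frame)
                if len(prot) < SEED_WORD:
                    continue
                index = _kmer_index(prot)
                for qid, qseq in qlist:
                    cutoff = min_raw_score(evalue_max, len(qseq), n_aa, params)
                    for w_lo, w_hi in _seed_windows(qseq, index, len(prot)):
                        window = list(prot[w_lo:w_hi])
                        for _ in range(max_hits_per_window):
                            sub = "".join(window)
                            score = aligner.score(qseq, sub)
                            if score < cutoff or score <= 0:
                                break
                            aln = aligner.align(qseq, sub)[0]
                            q_spans = tuple((int(a), int(b)) for a, b in aln.aligned[0])
                            s_spans = tuple((int(a), int(b)) for a, b in aln.aligned[1])
                            if not s_spans:
                                break
                            ident, alen = _identity(qseq, sub, q_spans, s_spans)
                            aa_lo = w_lo + s_spans[0][0]
                            aa_hi = w_lo + s_spans[-1][1]
                            nt_lo = frame + 3 * aa_lo
                            nt_hi = frame + 3 * aa_hi
                            if strand == "+":
                                start, end = nt_lo, nt_hi
                            else:
                                start, end = L - nt_hi, L - nt_lo
                            hits.append(SearchHit(
                                query_id=qid, scaffold_id=scaf_id,
                                start=start, end=end, strand=strand,
                                frame=frame, raw_score=float(score),
                                bit=bit_score(score, params),
                                evalue=evalue(score, len(qseq), n_aa, params),
                                query_start=q_spans[0][0], query_end=q_spans[-1][1],
                                identity=ident, length=alen))
                            for pos in range(s_spans[0][0], s_spans[-1][1]):
                                window[pos] = "*"
    hits.sort(key=lambda h: (h.scaffold_id, h.start, h.end, h.query_id))
    return hits


def hits_to_tsv(hits: Sequence[SearchHit]) -> str:
    """Render hits in BLAST outfmt-6 column order."""
    lines = []
    for h in hits:
        lines.append("\t".join(str(x) for x in (
            h.query_id, h.scaffold_id, round(100.0 * h.identity, 2), h.length,
            "-", "-",
            h.query_start + 1, h.query_end,
            h.start + 1, h.end,
            f"{h.evalue:.2e}", round(h.bit, 1))))
    return "\n".join(lines) + ("\n" if lines else "")
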