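"""Frameshift-aware local alignment of a protein against a DNA region.

The dynamic program aligns protein residues to codons read from the DNA,
allowing the reading frame to switch mid-alignment at a fixed penalty
(codon steps of 2 or 4 nucleotides instead of 3). In-frame stop codons are
scored like the BLOSUM62 ``*`` column (-4 against every residue), so
alignments extend through premature stops, and every stop and frame switch
inside the aligned blocks is reported. This is the evidence substrate for
"contains at least a stop codon or frameshift" pseudogene calls and for
the decay simulator's detectability checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_X_CODE = _AA_INDEX["X"]
STOP_CODE = _AA_INDEX["*"]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_FRAMESHIFT_PENALTY = -15  # below ~2 gap opens: real shifts beat forced gaps
DEFAULT_GAP_PENALTY = -12         # per codon / per residue, linear


def _blosum62_matrix() -> np.ndarray:
    sub = substitution_matrices.load("BLOSUM62")
    assert str(sub.alphabet) == PROTEIN_ALPHABET
    return np.asarray(sub, dtype=np.int32)


_BLOSUM62 = _blosum62_matrix()


def _codon_aa_table() -> np.ndarray:
    """64-entry table mapping codon index 16*a+4*b+c to protein code."""
    from fishor.search.translate import translate

    bases = "ACGT"
    table = np.empty(64, dtype=np.int8)
    for i, b1 in enumerate(bases):
        for j, b2 in enumerate(bases):
            for k, b3 in enumerate(bases):
                aa = translate(b1 + b2 + b3)
                table[16 * i + 4 * j + k] = _AA_INDEX[aa]
    return table


_CODON_AA = _codon_aa_table()


def encode_protein(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, _X_CODE) for aa in protein.upper()], dtype=np.int8)


def encode_dna(dna: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(nt, 4) for nt in dna.upper()], dtype=np.int8)


@njit(cache=True)
def _aa_of(dna, j):
    """Protein code of the codon ending at nucleotide position j (1-based end)."""
    b1 = dna[j - 3]
    b2 = dna[j - 2]
    b3 = dna[j - 1]
    if b1 > 3 or b2 > 3 or b3 > 3:
        return _X_CODE
    return _CODON_AA[16 * b1 + 4 * b2 + b3]


@njit(cache=True)
def _fs_score_kernel(prot, dna, sub, fs_pen, gap_pen):
    """Best local frameshift-aware alignment score (no traceback).

    Cells H[i, j]: best score of an alignment ending with prot[:i] vs
    dna[:j]. Codon steps consume 3 nt (in frame) or 2/4 nt (frame switch,
    penalized); gaps consume one residue or one codon.
    """
    m = prot.shape[0]
    n = dna.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        p = prot[i - 1]
        for j in range(n + 1):
            s = 0
            if j >= 3:
                aa = _aa_of(dna, j)
                match = sub[p, aa]
                v = prev[j - 3] + match
                if v > s:
                    s = v
                v = prev[j - 2] + match + fs_pen
                if v > s:
                    s = v
                if j >= 4:
                    v = prev[j - 4] + match + fs_pen
                    if v > s:
                        s = v
                v = cur[j - 3] + gap_pen  # codon unmatched in DNA
                if v > s:
                    s = v
            v = prev[j] + gap_pen  # residue unmatched in protein
            if v > s:
                s = v
            cur[j] = s
            if s > best:
                best = s
        prev, cur = cur, prev
    return best


@njit(cache=True)
def _fs_align_kernel(prot, dna, sub, fs_pen, gap_pen):
    """Full DP with traceback pointers; returns (H, ptr, best_i, best_j)."""
    m = prot.shape[0]
    n = dna.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    # ptr codes: 0 stop, 1 diag3, 2 fs2, 3 fs4, 4 codon-gap, 5 residue-gap
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        p = prot[i - 1]
        for j in range(n + 1):
            s = 0
            move = 0
            if j >= 3:
                aa = _aa_of(dna, j)
                match = sub[p, aa]
                v = H[i - 1, j - 3] + match
                if v > s:
                    s = v
                    move = 1
                v = H[i - 1, j - 2] + match + fs_pen
                if v > s:
                    s = v
                    move = 2
                if j >= 4:
                    v = H[i - 1, j - 4] + match + fs_pen
                    if v > s:
                        s = v
                        move = 3
                v = H[i, j - 3] + gap_pen
                if v > s:
                    s = v
                    move = 4
            v = H[i - 1, j] + gap_pen
            if v > s:
                s = v
                move = 5
            H[i, j] = s
            ptr[i, j] = move
            if s > best:
                best = s
                bi = i
                bj = j
    return H, ptr, bi, bj


@dataclass
class CodonAlignment:
    """Chained protein-to-DNA alignment with frame bookkeeping.

    ``blocks`` are ``(q_start, q_end, s_start, s_end, frame)`` tuples with
    half-open protein (aa) and DNA (nt) coordinates; ``frame`` is the
    reading frame (start mod 3) of the block. ``stops`` and
    ``frameshifts`` hold nucleotide positions (codon starts / switch
    points) inside the aligned region.
    """

    reference_id: str
    score: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    blocks: list[tuple[int, int, int, int, int]] = field(default_factory=list)
    stops: list[int] = field(default_factory=list)
    frameshifts: list[int] = field(default_factory=list)
    # per-event alignment score on the weaker side of the event:
    # min(score accumulated before it, score gained after it)
    stop_support: list[int] = field(default_factory=list)
    frameshift_support: list[int] = field(default_factory=list)

    @property
    def has_lof(self) -> bool:
        """At least one in-frame stop codon or frame switch."""
        return bool(self.stops) or bool(self.frameshifts)


def frameshift_score(protein, dna,
                     frameshift_penalty: int = DEFAULT_FRAMESHIFT_PENALTY,
                     gap_penalty: int = DEFAULT_GAP_PENALTY) -> int:
    """Best frameshift-aware local alignment raw score (score only)."""
    prot = protein if isinstance(protein, np.ndarray) else encode_protein(protein)
    d = dna if isinstance(dna, np.ndarray) else encode_dna(dna)
    if prot.size == 0 or d.size == 0:
        return 0
    return int(_fs_score_kernel(prot, d, _BLOSUM62,
                                np.int32(frameshift_penalty), np.int32(gap_penalty)))


def frameshift_align(reference: str, region: str,
                     frameshift_penalty: int = DEFAULT_FRAMESHIFT_PENALTY,
                     gap_penalty: int = DEFAULT_GAP_PENALTY,
                     reference_id: str = "ref") -> CodonAlignment:
    """Align ``reference`` protein to ``region`` DNA allowing frame switches.

    Returns the best-scoring chained alignment together with all in-frame
    stop codons and all frame-switch positions inside the aligned blocks.

    Raises
    ------
    ValueError
        If the region is shorter than 30 nt.
    """
    if len(region) < 30:
        raise ValueError("region must be at least 30 nt long")
    prot = encode_protein(reference)
    d = encode_dna(region)
    H, ptr, bi, bj = _fs_align_kernel(prot, d, _BLOSUM62,
                                      np.int32(frameshift_penalty),
                                      np.int32(gap_penalty))
    score = int(H[bi, bj])
    aln = CodonAlignment(reference_id=reference_id, score=score,
                         query_interval=(0, 0), subject_interval=(0, 0))
    if score <= 0:
        return aln
    # Traceback, collecting codon steps (protein pos, nt end, step size,
    # score before the step, score after it).
    i, j = bi, bj
    steps = []  # (i, j_end, nt_consumed, before, after)
    while ptr[i, j] != 0:
        move = ptr[i, j]
        after = int(H[i, j])
        if move == 1:
            i2, j2 = i - 1, j - 3
        elif move == 2:
            i2, j2 = i - 1, j - 2
        elif move == 3:
            i2, j2 = i - 1, j - 4
        elif move == 4:
            i2, j2 = i, j - 3
        else:
            i2, j2 = i - 1, j
        if move in (1, 2, 3):
            consumed = {1: 3, 2: 2, 3: 4}[move]
            steps.append((i, j, consumed, int(H[i2, j2]), after))
        i, j = i2, j2
    steps.reverse()
    aln.query_interval = (i, bi)
    aln.subject_interval = (j, bj)
    # Stops, frame switches and frame-constant blocks.
    blocks: list[list[int]] = []  # [q0, q1, s0, s1, frame]
    for qi, jend, consumed, before, after in steps:
        codon_start = jend - 3
        support = min(before, score - after)
        if consumed != 3:
            aln.frameshifts.append(jend)
            aln.frameshift_support.append(support)
        if _aa_of(d, jend) == STOP_CODE:
            aln.stops.append(max(codon_start, 0))
            aln.stop_support.append(support)
        frame = max(codon_start, 0) % 3
        if blocks and blocks[-1][4] == frame and consumed == 3 and qi == blocks[-1][1] + 1:
            blocks[-1][1] = qi
            blocks[-1][3] = jend
        else:
            blocks.append([qi - 1, qi, max(codon_start, 0), jend, frame])
    aln.blocks = [tuple(b) for b in blocks]
    return aln
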