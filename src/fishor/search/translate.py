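"""Frame-wise translation of nucleotide sequences."""

from __future__ import annotations

from Bio.Data import CodonTable

_VALID_NT = set("ACGTN")


def _build_codon_map(code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_MAPS: dict[int, dict[str, str]] = {}


def translate(dna: str, frame: int = 0, code: int = 1) -> str:
    """Translate ``dna`` in reading frame ``frame`` (0, 1 or 2).

    Codons containing ``N`` translate to ``'X'``; stop codons to ``'*'``.
    Trailing nucleotides that do not fill a codon are dropped.

    Raises
    ------
    ValueError
        If ``frame`` is not 0/1/2 or the sequence contains characters
        outside ``{A, C, G, T, N}`` (case-insensitive).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    seq = dna.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
    if code not in _CODON_MAPS:
        _CODON_MAPS[code] = _build_codon_map(code)
    codon_map = _CODON_MAPS[code]
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(codon_map[codon])
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return dna.upper().translate(_COMPLEMENT)[::-1]
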