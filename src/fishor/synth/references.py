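"""Labeled reference CDS/protein sets and non-OR decoy receptors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fishor.search.translate import translate

FAMILIES = ("beta", "gamma", "delta", "epsilon", "zeta", "eta", "alpha")
_FAMILY_ALIASES = {
    "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "α": "alpha",
}

_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ReferenceRecord:
    """One labeled reference gene: CDS (start..stop, no internal stops)."""

    id: str
    family: str | None
    cds: str

    @property
    def protein(self) -> str:
        return translate(self.cds)[:-1]  # drop trailing '*'


@dataclass
class ReferenceSet:
    records: list[ReferenceRecord] = field(default_factory=list)
    decoys: list[ReferenceRecord] = field(default_factory=list)

    def proteins(self) -> dict[str, str]:
        return {r.id: r.protein for r in self.records}

    def decoy_proteins(self) -> dict[str, str]:
        return {r.id: r.protein for r in self.decoys}

    def by_family(self) -> dict[str, list[ReferenceRecord]]:
        out: dict[str, list[ReferenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.family, []).append(r)
        return out


def canonical_family(label: str) -> str:
    fam = _FAMILY_ALIASES.get(label, label)
    if fam not in FAMILIES:
        raise ValueError(f"unknown family {label!r}")
    return fam


def _random_codon(rng, exclude_stops=True) -> str:
    while True:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, size=3))
        if not (exclude_stops and codon in _STOPS):
            return codon


def random_cds(rng, protein_length: int) -> str:
    """Random CDS: ATG + (protein_length - 1) non-stop codons + stop."""
    body = "".join(_random_codon(rng) for _ in range(protein_length - 1))
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + body + stop


def mutate_cds(cds: str, divergence: float, rng) -> str:
    """Apply ~``divergence`` substitutions/site, preserving the open frame.

    The start codon and terminal stop are kept; any codon that would
    become a stop is re-drawn. Substitution count per codon is binomial,
    matching a Jukes-Cantor-style process at low divergence.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    out = [codons[0]]
    for codon in codons[1:-1]:
        for _ in range(20):  # retry budget to avoid stops
            new = list(codon)
            nmut = rng.binomial(3, min(divergence, 1.0))
            if nmut:
                pos = rng.choice(3, size=nmut, replace=False)
                for p in pos:
                    choices = [b for b in _NT if b != new[p]]
                    new[p] = choices[int(rng.integers(3))]
            cand = "".join(new)
            if cand not in _STOPS:
                out.append(cand)
                break
        else:
            out.append(codon)
    out.append(codons[-1])
    return "".join(out)


def make_reference_set(families, n_per_family: int, protein_length: int = 310,
                       divergence: float = 0.05, between_divergence: float = 0.4,
                       n_decoys: int = 7, seed: int = 0) -> ReferenceSet:
    """Build a labeled reference set plus a disjoint decoy set.

    Family ancestors diverge from a common root at ``between_divergence``
    substitutions/site; members within a family diverge from their
    ancestor at ``divergence``. Decoys are independent random
    receptor-length CDS, so they score far below any true reference.
    """
    if not families:
        raise ValueError("family list must be non-empty")
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    if divergence >= between_divergence:
        raise ValueError("within-family divergence must be < between-family")
    fams = [canonical_family(f) for f in families]
    rng = np.random.default_rng(seed)
    root = random_cds(rng, protein_length)
    records = []
    for fam in fams:
        ancestor = mutate_cds(root, between_divergence, rng)
        for i in range(n_per_family):
            cds = mutate_cds(ancestor, divergence, rng)
            records.append(ReferenceRecord(id=f"{fam}_{i + 1}", family=fam, cds=cds))
    decoys = [ReferenceRecord(id=f"decoy{i + 1}", family=None,
                              cds=random_cds(rng, protein_length))
              for i in range(n_decoys)]
    return ReferenceSet(records=records, decoys=decoys)
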