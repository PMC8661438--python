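"""Genome construction with implanted gene loci of known class.

Builds multi-scaffold genomes of i.i.d. intergenic sequence at a
configurable GC content and implants four classes of loci: intact genes,
pseudogenes carrying introduced premature stops and/or frameshifts,
truncated remnants (clipped, no LoF) and scaffold-edge fragments. The
truth table records every placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fishor.search.translate import revcomp
from fishor.synth.references import ReferenceSet, mutate_cds

_STOPS = {"TAA", "TAG", "TGA"}


class CapacityError(ValueError):
    """The scaffold plan cannot host the requested implants."""


@dataclass
class ImplantPlan:
    n_functional: int = 0
    n_pseudo: int = 0
    n_truncated: int = 0
    n_edge: int = 0
    scaffold_sizes: tuple[int, ...] = (50_000,)
    min_gap: int = 2500
    edge_offset: int = 10       # bp between an edge locus and the scaffold end
    end_margin: int = 500       # keep mid-scaffold loci this far from ends
    gc: float = 0.41
    divergence: float = 0.0     # substitutions/site between implant and its source

    def __post_init__(self):
        counts = (self.n_functional, self.n_pseudo, self.n_truncated, self.n_edge)
        if any(c < 0 for c in counts):
            raise ValueError("plan counts must be non-negative")


@dataclass
class LofModel:
    """Loss-of-function mutations introduced per pseudogene."""

    n_stops: int = 1
    n_frameshifts: int = 1
    middle_fraction: float = 0.8   # LoF positions restricted to the middle 80%


@dataclass
class ImplantedLocus:
    """Truth-table row (0-based half-open forward-strand coordinates)."""

    scaffold: str
    start: int
    end: int
    strand: str
    cls: str            # functional | pseudogene | truncated | edge
    family: str
    source_id: str
    seq: str            # gene-orientation sequence as implanted


@dataclass
class SyntheticGenome:
    scaffolds: list[tuple[str, str]] = field(default_factory=list)
    truth: list[ImplantedLocus] = field(default_factory=list)

    def truth_counts(self) -> dict[str, int]:
        counts = {"functional": 0, "pseudogene": 0, "truncated": 0, "edge": 0}
        for loc in self.truth:
            counts[loc.cls] += 1
        return counts


def max_orf_length(seq: str) -> int:
    """Longest start-to-stop ORF (nt, stop included) over 6 frames."""
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            start = None
            for i in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[i:i + 3]
                if codon in _STOPS:
                    if start is not None:
                        best = max(best, i + 3 - start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
    return best


def _random_dna(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def _pseudogenize(cds: str, lof: LofModel, rng, max_orf_guard: int = 750) -> str:
    """Introduce premature stops/frameshifts; guarantee no long ORF survives."""
    n_codons = len(cds) // 3
    lo_c = int(n_codons * (1 - lof.middle_fraction) / 2)
    hi_c = int(n_codons * (1 + lof.middle_fraction) / 2)
    for _ in range(100):
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for _ in range(lof.n_stops):
            pos = int(rng.integers(max(lo_c, 1), hi_c))
            codons[pos] = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        seq = "".join(codons)
        for _ in range(lof.n_frameshifts):
            span = len(seq)
            lo = int(span * (1 - lof.middle_fraction) / 2)
            hi = int(span * (1 + lof.middle_fraction) / 2)
            pos = int(rng.integers(lo, hi))
            length = 1 + int(rng.integers(2))  # 1 or 2 nt: never a multiple of 3
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + length:]
            else:
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
                seq = seq[:pos] + ins + seq[pos:]
        if (lof.n_stops + lof.n_frameshifts) == 0 or max_orf_length(seq) < max_orf_guard:
            return seq
    raise RuntimeError("failed to produce a pseudogene without a long ORF")


def _clip(cds: str, rng, min_len: int = 300, max_len: int = 700) -> tuple[str, str]:
    """Clipped copy with no introduced internal LoF.

    5'-clipped fragments keep the terminal stop. 3'-clipped fragments are
    trimmed to a codon boundary and terminated with a stop codon so that
    the fragment cannot read through into flanking sequence (which would
    make the truth class ill-defined). Returns (fragment, clipped_side).
    """
    max_len = min(max_len, len(cds) - 3)
    length = int(rng.integers(min_len, max_len + 1))
    if rng.random() < 0.5:
        return cds[len(cds) - length:], "5prime"
    length -= length % 3
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return cds[:length - 3] + stop, "3prime"


def implant_genome(refs: ReferenceSet, plan: ImplantPlan,
                   lof_model: LofModel | None = None, seed: int = 0) -> SyntheticGenome:
    """Build a genome implementing ``plan`` with ground truth recorded.

    Pseudogenes carry >= 1 introduced premature stop and/or frameshift
    (indel length 1 or 2); truncated loci are 5'- or 3'-clipped intact
    copies; edge loci are clipped copies placed within
    ``plan.edge_offset`` bp of a scaffold end.
    """
    lof = lof_model or LofModel()
    if lof.n_stops + lof.n_frameshifts < 1 and plan.n_pseudo > 0:
        raise ValueError("lof_model must introduce at least one LoF mutation")
    rng = np.random.default_rng(seed)
    sources = refs.records
    if not sources and (plan.n_functional + plan.n_pseudo
                        + plan.n_truncated + plan.n_edge) > 0:
        raise ValueError("reference set is empty")

    def draw_gene():
        src = sources[int(rng.integers(len(sources)))]
        cds = mutate_cds(src.cds, plan.divergence, rng) if plan.divergence > 0 else src.cds
        return src, cds

    def make_builder(cls: str, cds: str):
        if cls == "functional":
            return lambda: cds
        if cls == "pseudogene":
            return lambda: _pseudogenize(cds, lof, rng)
        return lambda: _clip(cds, rng)[0]

    # (cls, builder, family, source); builders allow in-context resampling.
    # Non-functional remnants derive from sources already used functionally:
    # pass 2 mines them with the species' own gene set, so remnants of
    # families absent from the functional repertoire are undetectable by
    # design (a genuine limitation of the two-pass method).
    inserts: list[tuple[str, object, str, str]] = []
    used_sources: list = []
    for _ in range(plan.n_functional):
        src, cds = draw_gene()
        used_sources.append(src)
        inserts.append(("functional", make_builder("functional", cds),
                        src.family, src.id))

    def draw_remnant():
        if used_sources:
            src = used_sources[int(rng.integers(len(used_sources)))]
            cds = (mutate_cds(src.cds, plan.divergence, rng)
                   if plan.divergence > 0 else src.cds)
            return src, cds
        return draw_gene()

    for cls, count in (("pseudogene", plan.n_pseudo),
                       ("truncated", plan.n_truncated)):
        for _ in range(count):
            src, cds = draw_remnant()
            inserts.append((cls, make_builder(cls, cds), src.family, src.id))
    edge_inserts: list[tuple[str, object, str, str]] = []
    for _ in range(plan.n_edge):
        src, cds = draw_remnant()
        edge_inserts.append(("edge", make_builder("edge", cds), src.family, src.id))

    n_scaf = len(plan.scaffold_sizes)
    if plan.n_edge > 2 * n_scaf:
        raise CapacityError("at most two edge loci fit per scaffold")

    scaffold_arrays = [list(_random_dna(rng, size, plan.gc))
                       for size in plan.scaffold_sizes]
    scaffold_ids = [f"scaffold{i + 1}" for i in range(n_scaf)]
    truth: list[ImplantedLocus] = []

    def context_clean(scaf_idx: int, start: int, placed: str, flank: int = 1000) -> bool:
        """No ORF longer than 750 nt may overlap a non-functional implant
        once it sits in its genomic context (read-through into flanks)."""
        arr = scaffold_arrays[scaf_idx]
        lo = max(0, start - flank)
        hi = min(len(arr), start + len(placed) + flank)
        window = "".join(arr[lo:start]) + placed + "".join(arr[start + len(placed):hi])
        return max_orf_length(window) <= 750

    def place(scaf_idx: int, pos_fn, cls: str, builder, family: str, source: str) -> int:
        """Build, position and splice one insert; resample non-functional
        inserts until no long ORF overlaps them in context. Returns the
        end coordinate of the placed locus."""
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(50):
            seq = builder()
            placed = seq if strand == "+" else revcomp(seq)
            start = pos_fn(len(placed))
            if cls == "functional" or context_clean(scaf_idx, start, placed):
                break
        else:
            raise RuntimeError("could not place a context-clean implant")
        end = start + len(placed)
        scaffold_arrays[scaf_idx][start:end] = list(placed)
        truth.append(ImplantedLocus(scaffold=scaffold_ids[scaf_idx], start=start,
                                    end=end, strand=strand, cls=cls,
                                    family=family, source_id=source, seq=seq))
        return end

    # Edge loci occupy scaffold ends.
    edge_slots = [(i, side) for i in range(n_scaf) for side in ("left", "right")]
    used_ends: set[tuple[int, str]] = set()
    for (cls, builder, family, source), (scaf_idx, side) in zip(edge_inserts, edge_slots):
        size = plan.scaffold_sizes[scaf_idx]
        if 950 + plan.edge_offset + plan.min_gap > size:
            raise CapacityError("scaffold too small for edge locus")
        if side == "left":
            pos_fn = lambda L: plan.edge_offset
        else:
            pos_fn = lambda L, s=size: s - plan.edge_offset - L
        place(scaf_idx, pos_fn, cls, builder, family, source)
        used_ends.add((scaf_idx, side))

    # Mid-scaffold loci: sequential placement with minimum gaps.
    order = list(rng.permutation(len(inserts)))
    max_insert = 950  # CDS length plus indel slack
    cursors = []
    limits = []
    for i, size in enumerate(plan.scaffold_sizes):
        lo = plan.end_margin + (plan.min_gap if (i, "left") in used_ends else 0)
        hi = size - plan.end_margin - (plan.min_gap if (i, "right") in used_ends else 0)
        cursors.append(lo)
        limits.append(hi)
    scaf_idx = 0
    for k in order:
        cls, builder, family, source = inserts[k]
        while scaf_idx < n_scaf and cursors[scaf_idx] + max_insert > limits[scaf_idx]:
            scaf_idx += 1
        if scaf_idx >= n_scaf:
            raise CapacityError("scaffolds cannot host the requested plan")
        jitter = int(rng.integers(0, plan.min_gap // 4 + 1))
        base = cursors[scaf_idx]
        lim = limits[scaf_idx]
        pos_fn = (lambda L, b=base, j=jitter, lm=lim:
                  b + j if b + j + L <= lm else b)
        end = place(scaf_idx, pos_fn, cls, builder, family, source)
        cursors[scaf_idx] = end + plan.min_gap

    scaffolds = [(sid, "".join(arr)) for sid, arr in zip(scaffold_ids, scaffold_arrays)]
    truth.sort(key=lambda loc: (loc.scaffold, loc.start))
    return SyntheticGenome(scaffolds=scaffolds, truth=truth)
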