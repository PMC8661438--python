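"""Two-pass gene mining: candidate regions, ORF validation, classification.

Pass 1 searches the genome with an external labeled reference set at a
permissive e-value, extracts long ORFs from extended best-hit regions and
validates them against the references versus non-OR decoys; survivors are
the functional set. Pass 2 re-searches the genome with the species' own
functional genes at a stringent e-value; non-overlapping best-hit regions
that do not overlap functional loci are classified as edge, pseudogene or
truncated in that precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from fishor.annotation.records import ORGeneRecord, ORRepertoire
from fishor.search.align import DEFAULT_KA, KarlinAltschulParams, local_score
from fishor.search.frameshift import frameshift_align, frameshift_score
from fishor.search.translate import revcomp, translate
from fishor.search.translated_search import SearchHit, as_scaffolds, search_translated

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class AnnotationParams:
    evalue1: float = 1e-10        # pass-1 (external references)
    evalue2: float = 1e-20        # pass-2 (species' own functional set)
    extension: int = 1000         # bp added on both sides of pass-1 regions
    min_orf: int = 750            # ORFs must be strictly longer than this (nt)
    edge_distance: int = 30       # bp from scaffold end for the edge call
    min_hit_len: int = 60         # pass-2 regions shorter than this are noise
    ka: KarlinAltschulParams = field(default_factory=lambda: DEFAULT_KA)


@dataclass
class Region:
    """A merged best-hit region on one scaffold strand."""

    scaffold: str
    start: int
    end: int
    strand: str
    best_query: str
    best_bit: float
    hits: list[SearchHit] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


_CHAIN_MAX_GAP = 150       # nt between collinear HSPs of one query (stop/frameshift dip)
_CHAIN_MAX_OVERLAP = 10    # aa of tolerated query-span overlap when chaining


@dataclass
class _Chain:
    """Collinear HSPs of one query at one locus."""

    query_id: str
    start: int
    end: int
    bit: float
    hits: list[SearchHit]


def _chain_hits(group: list[SearchHit], strand: str) -> list[_Chain]:
    """Join HSPs of the same query that continue each other across a small
    subject gap (a frameshift or premature stop splits one locus into
    adjacent HSPs covering complementary parts of the query). Two distinct
    nearby loci are not joined: their query spans overlap instead."""
    chains: list[_Chain] = []
    group = sorted(group, key=lambda h: (h.start, h.end))
    for h in group:
        attached = False
        for ch in chains:
            if h.start - ch.end > _CHAIN_MAX_GAP or h.start < ch.end - 3 * _CHAIN_MAX_OVERLAP:
                continue
            last = ch.hits[-1]
            if strand == "+":
                collinear = h.query_start >= last.query_end - _CHAIN_MAX_OVERLAP
            else:
                collinear = h.query_end <= last.query_start + _CHAIN_MAX_OVERLAP
            if collinear:
                ch.hits.append(h)
                ch.end = max(ch.end, h.end)
                ch.bit += h.bit
                attached = True
                break
        if not attached:
            chains.append(_Chain(query_id=h.query_id, start=h.start, end=h.end,
                                 bit=h.bit, hits=[h]))
    return chains


def merge_best_hit_regions(hits: list[SearchHit]) -> list[Region]:
    """Cluster overlapping hits (strand-aware) into non-overlapping regions.

    HSPs of each query are first chained across frameshift/stop dips; then
    overlapping chains are clustered, the best chain (highest summed bit
    score) is chosen per cluster, and the region is the union of that
    chain's intervals. Regions from distinct clusters never overlap on the
    same strand.
    """
    regions: list[Region] = []
    by_key: dict[tuple[str, str, str], list[SearchHit]] = {}
    for h in hits:
        by_key.setdefault((h.scaffold_id, h.strand, h.query_id), []).append(h)
    chains_by_loc: dict[tuple[str, str], list[_Chain]] = {}
    for (scaf, strand, _qid), group in sorted(by_key.items()):
        chains_by_loc.setdefault((scaf, strand), []).extend(_chain_hits(group, strand))
    for (scaf, strand), chains in sorted(chains_by_loc.items()):
        chains.sort(key=lambda c: (c.start, c.end))
        cluster: list[_Chain] = []
        cluster_end = -1
        for ch in chains + [None]:
            if ch is not None and (not cluster or ch.start < cluster_end):
                cluster.append(ch)
                cluster_end = max(cluster_end, ch.end)
                continue
            if cluster:
                best = max(cluster, key=lambda c: c.bit)
                all_hits = [h for c in cluster for h in c.hits]
                regions.append(Region(scaffold=scaf, start=best.start, end=best.end,
                                      strand=strand, best_query=best.query_id,
                                      best_bit=best.bit, hits=all_hits))
            if ch is not None:
                cluster = [ch]
                cluster_end = ch.end
        regions.sort(key=lambda r: (r.scaffold, r.start))
    return regions


def find_candidate_regions(genome, or_refs, evalue_max: float = 1e-10,
                           extension: int = 1000,
                           params: KarlinAltschulParams = DEFAULT_KA) -> list[Region]:
    """Pass-1 candidate regions: merged best hits extended on both sides.

    Merging happens before extension; each region is then extended by
    ``extension`` bp upstream and downstream and clipped at scaffold
    bounds.
    """
    scaffolds = dict(as_scaffolds(genome))
    hits = search_translated(or_refs, genome, evalue_max, params=params)
    regions = merge_best_hit_regions(hits)
    for r in regions:
        r.start = max(0, r.start - extension)
        r.end = min(len(scaffolds[r.scaffold]), r.end + extension)
    return regions


@dataclass
class ORF:
    seq: str           # nucleotide sequence in gene orientation (incl. stop)
    frame: int
    strand: str
    start: int         # forward-strand coords within the searched region
    end: int

    @property
    def protein(self) -> str:
        return translate(self.seq)[:-1]


def extract_orfs(region_seq: str, min_len: int = 750) -> list[ORF]:
    """All maximal start-to-stop ORFs strictly longer than ``min_len``.

    Both strands, all three frames; an ORF runs from the first ATG after
    the previous stop through its stop codon (inclusive). Coordinates are
    forward-strand positions within ``region_seq``.
    """
    L = len(region_seq)
    out: list[ORF] = []
    for strand in ("+", "-"):
        seq = region_seq if strand == "+" else revcomp(region_seq)
        for frame in range(3):
            start = None
            for i in range(frame, L - 2, 3):
                codon = seq[i:i + 3]
                if codon in _STOPS:
                    if start is not None and (i + 3 - start) > min_len:
                        orf_seq = seq[start:i + 3]
                        if strand == "+":
                            s, e = start, i + 3
                        else:
                            s, e = L - (i + 3), L - start
                        out.append(ORF(seq=orf_seq, frame=frame, strand=strand,
                                       start=s, end=e))
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
    out.sort(key=lambda o: (o.start, o.end))
    return out


def validate_or(orf, or_refs, decoy_refs) -> tuple[bool, dict]:
    """Accept an ORF iff it scores strictly better against the OR
    references than against the decoy set (ties are rejected)."""
    if isinstance(orf, ORF):
        protein = orf.protein
    else:
        protein = str(orf)
    if not protein:
        raise ValueError("empty ORF")
    ors = _as_ref_proteins(or_refs)
    decoys = _as_ref_proteins(decoy_refs)
    if not ors or not decoys:
        raise ValueError("reference and decoy sets must be non-empty")
    best_or_id, best_or = max(((rid, local_score(protein, p)) for rid, p in ors.items()),
                              key=lambda kv: kv[1])
    best_decoy = max(local_score(protein, p) for p in decoys.values())
    accepted = best_or > best_decoy
    return accepted, {"best_or_id": best_or_id, "best_or_score": best_or,
                      "best_decoy_score": best_decoy}


def _as_ref_proteins(refs) -> dict[str, str]:
    if isinstance(refs, dict):
        return refs
    if hasattr(refs, "proteins"):
        return refs.proteins()
    return {r.id: r.protein for r in refs}


def dedup_identical(records: list[ORGeneRecord]) -> tuple[list[ORGeneRecord], int]:
    """Remove exact nucleotide duplicates; the representative is the first
    record in (scaffold, start) order. Returns (survivors, n_removed)."""
    ordered = sorted(records, key=lambda r: (r.scaffold, r.start, r.end))
    seen: dict[str, ORGeneRecord] = {}
    for rec in ordered:
        if rec.seq not in seen:
            seen[rec.seq] = rec
    survivors = sorted(seen.values(), key=lambda r: (r.scaffold, r.start))
    return survivors, len(records) - len(survivors)


_MIN_LOF_SUPPORT = 40   # raw score required on the weaker side of a LoF event
_CLASSIFY_PAD = 300     # nt of context added around a region before classification


def classify_nonfunctional(region: Region, scaffold_len: int,
                           functional_intervals: list[tuple[str, int, int]],
                           reference_protein: str, region_seq: str,
                           edge_distance: int = 30,
                           min_lof_support: int = _MIN_LOF_SUPPORT) -> tuple[str, dict]:
    """Classify a pass-2 region as edge, pseudogene or truncated.

    Precedence: (1) edge when the region lies closer than
    ``edge_distance`` bp to a scaffold end; (2) pseudogene when the
    frameshift-aware alignment to ``reference_protein`` reports at least
    one supported in-frame stop or frame switch; (3) truncated otherwise.
    A LoF event is supported when the alignment scores at least
    ``min_lof_support`` on each side of it — a genuine mid-gene LoF sits
    between two homologous blocks, whereas chance alignment tails creeping
    past a fragment boundary have negligible score on one side.
    """
    for scaf, s, e in functional_intervals:
        if scaf == region.scaffold and region.start < e and region.end > s:
            raise ValueError("region overlaps a functional locus; "
                             "such hits must be discarded upstream")
    if min(region.start, scaffold_len - region.end) < edge_distance:
        return "edge", {"distance_to_end": min(region.start, scaffold_len - region.end)}
    oriented = region_seq if region.strand == "+" else revcomp(region_seq)
    aln = frameshift_align(reference_protein, oriented)
    stops = [p for p, sup in zip(aln.stops, aln.stop_support)
             if sup >= min_lof_support]
    shifts = [p for p, sup in zip(aln.frameshifts, aln.frameshift_support)
              if sup >= min_lof_support]
    evidence = {"stops": stops, "frameshifts": shifts, "score": aln.score,
                "unsupported_lof": len(aln.stops) + len(aln.frameshifts)
                                   - len(stops) - len(shifts)}
    if stops or shifts:
        return "pseudogene", evidence
    return "truncated", evidence


def assign_family(seq, labeled_refs, pseudo: bool = False) -> tuple[str | None, dict]:
    """Family of the best-scoring labeled reference.

    Protein-level alignment for intact sequences; frameshift-aware
    translated scoring for pseudogenes. Ties break by reference id order
    (scores are integers, so "higher percent identity" reduces to the
    deterministic id order among equal scorers).
    """
    records = labeled_refs.records if hasattr(labeled_refs, "records") else labeled_refs
    best = None
    for ref in sorted(records, key=lambda r: r.id):
        if pseudo:
            score = frameshift_score(ref.protein, seq)
        else:
            score = local_score(seq, ref.protein)
        if best is None or score > best[1]:
            best = (ref.family, score, ref.id)
    if best is None or best[1] <= 0:
        return None, {"best_ref": None, "score": 0}
    return best[0], {"best_ref": best[2], "score": best[1]}


def annotate_genome(genome, or_refs, decoy_refs=None,
                    params: AnnotationParams | None = None,
                    species_id: str = "synthetic") -> ORRepertoire:
    """Run the full two-pass mining pipeline on one genome.

    ``or_refs`` may be a ReferenceSet (decoys taken from it when
    ``decoy_refs`` is None) or a list of labeled reference records.
    """
    params = params or AnnotationParams()
    if decoy_refs is None and hasattr(or_refs, "decoys"):
        decoy_refs = or_refs.decoys
    if decoy_refs is None:
        raise ValueError("decoy references are required")
    scaffolds = dict(as_scaffolds(genome))
    ref_proteins = _as_ref_proteins(or_refs)
    decoy_proteins = _as_ref_proteins(decoy_refs)

    # ---- pass 1: functional gene discovery -------------------------------
    regions = find_candidate_regions(genome, ref_proteins, params.evalue1,
                                     params.extension, params.ka)
    candidates: list[ORGeneRecord] = []
    seen_coords: set[tuple[str, int, int, str]] = set()
    for region in regions:
        region_seq = scaffolds[region.scaffold][region.start:region.end]
        for orf in extract_orfs(region_seq, params.min_orf):
            abs_start = region.start + orf.start
            abs_end = region.start + orf.end
            key = (region.scaffold, abs_start, abs_end, orf.strand)
            if key in seen_coords:
                continue
            seen_coords.add(key)
            accepted, evidence = validate_or(orf, ref_proteins, decoy_proteins)
            if not accepted:
                continue
            family, fam_ev = assign_family(orf.protein, or_refs)
            evidence.update(fam_ev)
            candidates.append(ORGeneRecord(
                id="", scaffold=region.scaffold, start=abs_start, end=abs_end,
                strand=orf.strand, cls="functional", family=family,
                seq=orf.seq, evidence=evidence))
    functional = _resolve_overlaps(candidates)
    functional, n_removed = dedup_identical(functional)
    for i, rec in enumerate(functional):
        rec.id = f"{species_id}.func{i + 1}"

    records: list[ORGeneRecord] = list(functional)

    # ---- pass 2: nonfunctional loci --------------------------------------
    if functional:
        queries = {rec.id: translate(rec.seq)[:-1] for rec in functional}
        hits2 = search_translated(queries, genome, params.evalue2, params=params.ka)
        func_intervals = [(r.scaffold, r.start, r.end) for r in functional]
        counter = {"edge": 0, "pseudogene": 0, "truncated": 0}
        for region in merge_best_hit_regions(hits2):
            if any(scaf == region.scaffold and region.start < e and region.end > s
                   for scaf, s, e in func_intervals):
                continue
            if region.end - region.start < params.min_hit_len:
                continue
            scaf_seq = scaffolds[region.scaffold]
            region_seq = scaf_seq[region.start:region.end]
            # Classify on padded context so LoF evidence just outside the
            # reported hit interval (sub-threshold flanking blocks) is seen;
            # the pad never crosses a functional locus.
            pad_lo = max(0, region.start - _CLASSIFY_PAD)
            pad_hi = min(len(scaf_seq), region.end + _CLASSIFY_PAD)
            for scaf, s, e in func_intervals:
                if scaf == region.scaffold:
                    if e <= region.start:
                        pad_lo = max(pad_lo, e)
                    if s >= region.end:
                        pad_hi = min(pad_hi, s)
            cls, evidence = classify_nonfunctional(
                region, len(scaf_seq), func_intervals,
                queries[region.best_query], scaf_seq[pad_lo:pad_hi],
                params.edge_distance)
            family, fam_ev = assign_family(
                region_seq if region.strand == "+" else revcomp(region_seq),
                or_refs, pseudo=True)
            evidence.update(fam_ev)
            counter[cls] += 1
            records.append(ORGeneRecord(
                id=f"{species_id}.{cls}{counter[cls]}", scaffold=region.scaffold,
                start=region.start, end=region.end, strand=region.strand,
                cls=cls, family=family, seq=region_seq, evidence=evidence))

    records.sort(key=lambda r: (r.scaffold, r.start))
    return ORRepertoire(species_id=species_id, records=records)


def _resolve_overlaps(candidates: list[ORGeneRecord]) -> list[ORGeneRecord]:
    """Keep the best-validated record among same-strand overlapping ones."""
    kept: list[ORGeneRecord] = []
    for rec in sorted(candidates,
                      key=lambda r: -r.evidence.get("best_or_score", 0.0)):
        clash = any(k.scaffold == rec.scaffold and k.strand == rec.strand
                    and rec.start < k.end and rec.end > k.start for k in kept)
        if not clash:
            kept.append(rec)
    kept.sort(key=lambda r: (r.scaffold, r.start))
    return kept
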