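"""Annotation pipeline: QC, candidate regions, ORFs, validation,
classification and the end-to-end two-pass miner."""

import numpy as np
import pytest

from fishor.annotation import (AnnotationParams, annotate_genome, dedup_identical,
                               extract_orfs, find_candidate_regions, qc_genome,
                               validate_or)
from fishor.annotation.mining import (Region, classify_nonfunctional,
                                      merge_best_hit_regions, assign_family)
from fishor.annotation.records import ORGeneRecord
from fishor.search.translate import revcomp, translate
from fishor.search.translated_search import SearchHit
from fishor.synth import ImplantPlan, implant_genome
from fishor.synth.references import random_cds


# ------------------------------------------------------------------ qc


def test_qc_expected_size_formula():
    rec = qc_genome(0.978e9, 1.0, 0.95, 1.5)
    assert rec.expected_size == pytest.approx(0.978e9)
    assert rec.size_congruent is True
    assert rec.completeness_ok is True
    assert rec.passed


def test_qc_completeness_threshold():
    assert qc_genome(1e9, 1.0, 0.89, 1.5).completeness_ok is False
    assert qc_genome(1e9, 1.0, 0.90, 1.5).completeness_ok is True


def test_qc_size_incongruent():
    rec = qc_genome(3e9, 1.0, 0.99, 1.5)
    assert rec.size_congruent is False
    assert not rec.passed


def test_qc_missing_cvalue():
    rec = qc_genome(1e9, None, 0.95, 1.5)
    assert rec.size_congruent is None
    assert rec.completeness_ok is True
    assert not rec.passed


# ------------------------------------------------------- candidate regions


def test_region_extension_and_coverage(refs):
    plan = ImplantPlan(n_functional=1, scaffold_sizes=(20_000,), divergence=0.0)
    g = implant_genome(refs, plan, seed=6)
    loc = g.truth[0]
    regions = find_candidate_regions(g, refs.proteins(), 1e-10, extension=1000)
    assert len(regions) >= 1
    covering = [r for r in regions if r.start < loc.end and r.end > loc.start]
    assert covering
    r = covering[0]
    assert r.start <= max(0, loc.start - 900)  # extended (clipped at 0)
    assert r.end >= min(loc.end + 900, 20_000)


def test_region_clipped_at_scaffold_bounds(refs):
    plan = ImplantPlan(n_functional=1, n_edge=1, scaffold_sizes=(15_000,),
                       divergence=0.0)
    g = implant_genome(refs, plan, seed=12)
    regions = find_candidate_regions(g, refs.proteins(), 1e-10, extension=1000)
    size = len(g.scaffolds[0][1])
    for r in regions:
        assert 0 <= r.start < r.end <= size


def _hit(q, s, start, end, strand="+", bit=100.0, qs=0, qe=100):
    return SearchHit(query_id=q, scaffold_id=s, start=start, end=end,
                     strand=strand, frame=0, raw_score=bit / 0.385, bit=bit,
                     evalue=1e-30, query_start=qs, query_end=qe,
                     identity=0.9, length=qe - qs)


def test_merge_nearby_loci_stay_separate():
    """Two loci 100 bp apart hit by the same full-span query do not merge."""
    hits = [_hit("q", "s", 1000, 1900, qs=0, qe=300),
            _hit("q", "s", 2000, 2900, qs=0, qe=300)]
    regions = merge_best_hit_regions(hits)
    assert len(regions) == 2


def test_merge_chains_split_hsps_of_one_query():
    """Complementary query spans across a small gap chain into one region."""
    hits = [_hit("q", "s", 1000, 1450, qs=0, qe=150),
            _hit("q", "s", 1500, 1950, qs=150, qe=300)]
    regions = merge_best_hit_regions(hits)
    assert len(regions) == 1
    assert regions[0].interval == (1000, 1950)


def test_merge_overlapping_queries_pick_best():
    hits = [_hit("a", "s", 1000, 1900, bit=200.0),
            _hit("b", "s", 1100, 1800, bit=150.0)]
    regions = merge_best_hit_regions(hits)
    assert len(regions) == 1
    assert regions[0].best_query == "a"


# ------------------------------------------------------------------ ORFs


def test_extract_orfs_finds_intact_cds(rng):
    cds = random_cds(rng, 310)  # 933 nt
    region = "C" * 100 + cds + "C" * 100
    orfs = extract_orfs(region, 750)
    assert any(o.seq == cds and o.strand == "+" for o in orfs)


def test_extract_orfs_strictly_greater_than_threshold(rng):
    cds = random_cds(rng, 249)  # 750 nt exactly, stop included
    assert len(cds) == 750
    region = "C" * 50 + cds + "C" * 50
    assert extract_orfs(region, 750) == []
    cds2 = random_cds(rng, 250)  # 753 nt
    region2 = "C" * 50 + cds2 + "C" * 50
    assert any(o.seq == cds2 for o in extract_orfs(region2, 750))


def test_extract_orfs_revcomp_flips_strand(rng):
    cds = random_cds(rng, 310)
    region = "C" * 90 + cds + "C" * 60
    fwd = extract_orfs(region, 750)
    rev = extract_orfs(revcomp(region), 750)
    L = len(region)
    fwd_set = {(o.start, o.end, o.strand) for o in fwd}
    mapped = {(L - o.end, L - o.start, "+" if o.strand == "-" else "-") for o in rev}
    assert fwd_set == mapped


# ------------------------------------------------------------------ validate


def test_validate_accepts_reference_copy(refs):
    rec = refs.records[0]
    accepted, ev = validate_or(rec.protein, refs.proteins(), refs.decoy_proteins())
    assert accepted
    assert ev["best_or_id"] == rec.id


def test_validate_rejects_decoy(refs):
    decoy = refs.decoys[0]
    accepted, _ = validate_or(decoy.protein, refs.proteins(), refs.decoy_proteins())
    assert not accepted


def test_validate_tie_is_rejected(refs):
    seq = refs.records[0].protein
    ors = {"r1": seq}
    decoys = {"d1": seq}  # identical: scores tie exactly
    accepted, ev = validate_or(seq, ors, decoys)
    assert not accepted
    assert ev["best_or_score"] == ev["best_decoy_score"]


def test_validate_empty_orf_raises(refs):
    with pytest.raises(ValueError):
        validate_or("", refs.proteins(), refs.decoy_proteins())


# ------------------------------------------------------------------ dedup


def _rec(seq, scaffold="s", start=0, end=None, cls="functional"):
    return ORGeneRecord(id="", scaffold=scaffold, start=start,
                        end=end or (start + len(seq)), strand="+", cls=cls,
                        family=None, seq=seq)


def test_dedup_removes_exact_duplicates():
    recs = [_rec("ATGAAA", start=100), _rec("ATGAAA", start=500)]
    out, removed = dedup_identical(recs)
    assert removed == 1
    assert out[0].start == 100  # representative = first by coordinate


def test_dedup_keeps_near_duplicates():
    out, removed = dedup_identical([_rec("ATGAAA", start=0), _rec("ATGAAC", start=50)])
    assert removed == 0
    assert len(out) == 2


def test_dedup_empty():
    assert dedup_identical([]) == ([], 0)


# ------------------------------------------------------------- classify


def _mk_region(start, end, strand="+", query="q"):
    return Region(scaffold="s", start=start, end=end, strand=strand,
                  best_query=query, best_bit=500.0)


def test_classify_edge_precedence(rng):
    cds = random_cds(rng, 310)
    protein = translate(cds)[:-1]
    region = _mk_region(10, 10 + 400)
    cls, ev = classify_nonfunctional(region, 20_000, [], protein, cds[:400],
                                     edge_distance=30)
    assert cls == "edge"


def test_classify_pseudogene_internal_stop(rng):
    cds = random_cds(rng, 310)
    protein = translate(cds)[:-1]
    mutated = cds[:450] + "TAA" + cds[453:-3]
    region = _mk_region(5000, 5000 + len(mutated))
    cls, ev = classify_nonfunctional(region, 20_000, [], protein, mutated)
    assert cls == "pseudogene"
    assert len(ev["stops"]) == 1


def test_classify_truncated_clean_fragment(rng):
    cds = random_cds(rng, 310)
    protein = translate(cds)[:-1]
    frag = cds[200:600]
    region = _mk_region(5000, 5400)
    cls, ev = classify_nonfunctional(region, 20_000, [], protein, frag)
    assert cls == "truncated"
    assert ev["stops"] == [] and ev["frameshifts"] == []


def test_classify_rejects_overlap_with_functional(rng):
    cds = random_cds(rng, 310)
    protein = translate(cds)[:-1]
    region = _mk_region(5000, 5400)
    with pytest.raises(ValueError):
        classify_nonfunctional(region, 20_000, [("s", 5300, 6000)], protein,
                               cds[:400])


# ------------------------------------------------------------- family


def test_assign_family_self_match(refs):
    rec = refs.records[0]
    fam, ev = assign_family(rec.protein, refs)
    assert fam == rec.family


def test_assign_family_pseudogene_frameshift_aware(refs, small_genome):
    for loc in small_genome.truth:
        if loc.cls == "pseudogene":
            fam, _ = assign_family(loc.seq, refs, pseudo=True)
            assert fam == loc.family


def test_assign_family_no_signal():
    from fishor.synth.references import ReferenceRecord

    refs = [ReferenceRecord(id="r", family="delta", cds="ATG" + "GCA" * 100 + "TAA")]
    fam, _ = assign_family("W" * 20, refs)
    assert fam is None or fam == "delta"  # weak garbage never scores above 0


# ------------------------------------------------------------- end-to-end


def test_annotate_small_genome_exact(refs, small_genome):
    rep = annotate_genome(small_genome, refs)
    assert rep.class_counts == small_genome.truth_counts()
    # families of functional records match the truth
    truth_functional = sorted((l.start, l.family) for l in small_genome.truth
                              if l.cls == "functional")
    found_functional = sorted((r.start, r.family) for r in rep.records
                              if r.cls == "functional")
    assert [f for _, f in truth_functional] == [f for _, f in found_functional]


def test_annotate_empty_genome(refs):
    rep = annotate_genome({"s1": "ACGT" * 2000}, refs)
    assert rep.class_counts == {"functional": 0, "pseudogene": 0,
                                "truncated": 0, "edge": 0}


def test_annotate_scaffold_order_invariant(refs, small_genome):
    rep1 = annotate_genome(small_genome, refs)
    reordered = list(reversed(small_genome.scaffolds))
    rep2 = annotate_genome(reordered, refs)
    assert rep1.class_counts == rep2.class_counts


def test_functional_records_never_overlap_same_strand(refs, small_genome):
    rep = annotate_genome(small_genome, refs)
    funcs = rep.of_class("functional")
    for i, a in enumerate(funcs):
        for b in funcs[i + 1:]:
            if a.scaffold == b.scaffold and a.strand == b.strand:
                assert a.end <= b.start or b.end <= a.start


def test_pass2_records_never_overlap_functional(refs, small_genome):
    rep = annotate_genome(small_genome, refs)
    funcs = rep.of_class("functional")
    for rec in rep.records:
        if rec.cls == "functional":
            continue
        for f in funcs:
            if f.scaffold == rec.scaffold:
                assert rec.end <= f.start or f.end <= rec.start


def test_round_trip_truth_recovery_divergence_zero(refs):
    """Truth table exactly recovered when implants equal their sources."""
    plan = ImplantPlan(n_functional=4, n_pseudo=2, n_truncated=1, n_edge=1,
                       scaffold_sizes=(35_000,), divergence=0.0)
    g = implant_genome(refs, plan, seed=17)
    rep = annotate_genome(g, refs)
    assert rep.class_counts == g.truth_counts()
    for loc in g.truth:
        match = [r for r in rep.records if r.scaffold == loc.scaffold
                 and r.start < loc.end and r.end > loc.start and r.cls == loc.cls]
        assert match, loc
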