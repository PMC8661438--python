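"""Synthetic-data generators: trees, histories, references, genomes, traits."""

import numpy as np
import pytest

from fishor.search import frameshift_align
from fishor.search.align import local_score
from fishor.synth import (CapacityError, ImplantPlan, LofModel, implant_genome,
                          make_reference_set, simulate_gene_history,
                          simulate_species_tree, simulate_traits)
from fishor.treeutils import node_depths, to_newick, vcv_matrix


# ------------------------------------------------------------- species tree


def test_two_tip_tree_is_forced():
    tree = simulate_species_tree(2, 100.0, 1)
    lengths = [leaf.edge.length for leaf in tree.leaf_node_iter()]
    assert lengths == pytest.approx([100.0, 100.0])


def test_ultrametric_crown_age():
    tree = simulate_species_tree(8, 250.0, 7)
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    assert max(tip_depths) == pytest.approx(250.0, abs=1e-9)
    assert min(tip_depths) == pytest.approx(250.0, abs=1e-9)


def test_species_tree_deterministic():
    assert (to_newick(simulate_species_tree(8, 250.0, 42))
            == to_newick(simulate_species_tree(8, 250.0, 42)))


def test_species_tree_invalid_args():
    with pytest.raises(ValueError):
        simulate_species_tree(1, 100.0, 0)
    with pytest.raises(ValueError):
        simulate_species_tree(4, 0.0, 0)


# ------------------------------------------------------------- gene history


def test_zero_rate_identity():
    tree = simulate_species_tree(6, 120.0, 3)
    hist = simulate_gene_history(tree, 10, 0.0, 0.0, seed=5)
    assert all(len(v) == 10 for v in hist.tip_inventory.values())
    assert all(b.gains == 0 and b.losses == 0 for b in hist.branches.values())


def test_ledger_conservation():
    tree = simulate_species_tree(10, 200.0, 11)
    for seed in range(5):
        hist = simulate_gene_history(tree, 8, 0.01, 0.008, seed=seed)
        for b in hist.branches.values():
            assert b.n_desc == b.n_anc + b.gains - b.losses
            assert b.n_desc >= 0
        # tip ledgers agree with the inventory
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            assert len(hist.tip_inventory[label]) == hist.branches[label].n_desc


def test_critical_process_preserves_mean_copy_number():
    """E[n(t)] = n0 when birth = death (Monte-Carlo oracle, 200 reps)."""
    tree = simulate_species_tree(2, 100.0, 1)
    totals = []
    for seed in range(200):
        hist = simulate_gene_history(tree, 100, 0.007, 0.007, seed=seed)
        totals.extend(len(v) for v in hist.tip_inventory.values())
    assert np.mean(totals) == pytest.approx(100.0, rel=0.10)


def test_pure_death_extinction():
    tree = simulate_species_tree(4, 50.0, 2)  # all paths >= 5 Myr
    hist = simulate_gene_history(tree, 5, 0.0, 10.0, seed=3)
    assert all(len(v) == 0 for v in hist.tip_inventory.values())
    assert hist.gene_tree is None


def test_gene_tree_tips_match_inventory():
    tree = simulate_species_tree(6, 150.0, 9)
    hist = simulate_gene_history(tree, 6, 0.01, 0.01, seed=13)
    labels = {leaf.taxon.label for leaf in hist.gene_tree.leaf_node_iter()}
    expected = {f"{sp}|{g}" for sp, genes in hist.tip_inventory.items() for g in genes}
    assert labels == expected


def test_negative_rates_rejected():
    tree = simulate_species_tree(4, 100.0, 1)
    with pytest.raises(ValueError):
        simulate_gene_history(tree, 5, -0.1, 0.0, seed=1)


# ------------------------------------------------------------- references


def test_reference_cds_construction(refs):
    for rec in refs.records:
        assert len(rec.cds) == 933
        assert rec.cds.startswith("ATG")
        assert rec.cds[-3:] in ("TAA", "TAG", "TGA")
        assert "*" not in rec.protein
        assert len(rec.protein) == 310


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def test_within_family_identity_exceeds_between(refs):
    by_fam = refs.by_family()
    within = []
    between = []
    fams = sorted(by_fam)
    for fam in fams:
        members = by_fam[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                within.append(_identity(members[i].protein, members[j].protein))
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            for a in by_fam[fams[i]]:
                for b in by_fam[fams[j]]:
                    between.append(_identity(a.protein, b.protein))
    assert np.mean(within) > np.mean(between)


def test_decoys_score_below_true_references(refs):
    ref_proteins = [r.protein for r in refs.records]
    best_decoy = max(local_score(d.protein, r) for d in refs.decoys
                     for r in ref_proteins)
    worst_or = min(max(local_score(a.protein, b) for b in ref_proteins
                       if b != a.protein) for a in refs.records)
    assert best_decoy < worst_or


def test_reference_set_validation():
    with pytest.raises(ValueError):
        make_reference_set([], 2)
    with pytest.raises(ValueError):
        make_reference_set(["delta"], 2, divergence=0.5, between_divergence=0.4)
    with pytest.raises(ValueError):
        make_reference_set(["nosuch"], 1)


# ------------------------------------------------------------- implant_genome


def test_all_zero_plan(refs):
    g = implant_genome(refs, ImplantPlan(scaffold_sizes=(5000,)), seed=1)
    assert g.truth == []
    assert len(g.scaffolds[0][1]) == 5000


def test_one_of_each_class(refs):
    plan = ImplantPlan(n_functional=1, n_pseudo=1, n_truncated=1, n_edge=1,
                       scaffold_sizes=(25_000,))
    g = implant_genome(refs, plan, LofModel(n_stops=1, n_frameshifts=0), seed=2)
    assert g.truth_counts() == {"functional": 1, "pseudogene": 1,
                                "truncated": 1, "edge": 1}


def test_truth_rows_within_scaffold_bounds(small_genome):
    sizes = {sid: len(seq) for sid, seq in small_genome.scaffolds}
    for loc in small_genome.truth:
        assert 0 <= loc.start < loc.end <= sizes[loc.scaffold]


def test_edge_locus_near_scaffold_end(small_genome):
    sizes = {sid: len(seq) for sid, seq in small_genome.scaffolds}
    for loc in small_genome.truth:
        if loc.cls == "edge":
            dist = min(loc.start, sizes[loc.scaffold] - loc.end)
            assert dist < 30


def test_pseudogenes_show_lof_against_source(refs, small_genome):
    by_id = {r.id: r for r in refs.records}
    for loc in small_genome.truth:
        if loc.cls == "pseudogene":
            aln = frameshift_align(by_id[loc.source_id].protein, loc.seq)
            assert aln.has_lof


def test_implanted_sequence_matches_scaffold(small_genome):
    from fishor.search.translate import revcomp

    scafs = dict(small_genome.scaffolds)
    for loc in small_genome.truth:
        placed = scafs[loc.scaffold][loc.start:loc.end]
        expected = loc.seq if loc.strand == "+" else revcomp(loc.seq)
        assert placed == expected


def test_capacity_error(refs):
    plan = ImplantPlan(n_functional=10, scaffold_sizes=(5000,))
    with pytest.raises(CapacityError):
        implant_genome(refs, plan, seed=1)


def test_implant_deterministic(refs):
    plan = ImplantPlan(n_functional=2, n_pseudo=1, scaffold_sizes=(20_000,))
    g1 = implant_genome(refs, plan, seed=7)
    g2 = implant_genome(refs, plan, seed=7)
    assert g1.scaffolds == g2.scaffolds
    assert [(l.start, l.cls) for l in g1.truth] == [(l.start, l.cls) for l in g2.truth]


# ------------------------------------------------------------- traits


def test_bm_sigma_zero_constant():
    tree = simulate_species_tree(6, 100.0, 2)
    vals = simulate_traits(tree, "BM", {"sigma2": 0.0, "root": 5.0}, seed=1)
    assert set(vals.values()) == {5.0}


def test_bm_tip_covariance_matches_analytic():
    """Empirical covariance over 2000 replicates equals sigma2 * C."""
    tree = simulate_species_tree(5, 80.0, 4)
    C, taxa = vcv_matrix(tree)
    draws = np.array([[simulate_traits(tree, "BM", {"sigma2": 1.0}, seed=s)[t]
                       for t in taxa] for s in range(2000)])
    emp = np.cov(draws.T)
    scale = np.sqrt(np.outer(np.diag(C), np.diag(C)))
    assert np.abs((emp - C) / scale).max() < 0.12  # Monte-Carlo tolerance


def test_mk_rate_zero_inherits_root():
    tree = simulate_species_tree(6, 100.0, 3)
    vals = simulate_traits(tree, "Mk", {"q01": 0.0, "q10": 0.0, "root_state": 1},
                           seed=2)
    assert set(vals.values()) == {1}


def test_traits_deterministic():
    tree = simulate_species_tree(6, 100.0, 3)
    a = simulate_traits(tree, "BM", {"sigma2": 1.0}, seed=11)
    b = simulate_traits(tree, "BM", {"sigma2": 1.0}, seed=11)
    assert a == b


def test_traits_invalid_params():
    tree = simulate_species_tree(4, 100.0, 1)
    with pytest.raises(ValueError):
        simulate_traits(tree, "lambda", {"lam": 1.5}, seed=0)
    with pytest.raises(ValueError):
        simulate_traits(tree, "OU", {"alpha": -1.0}, seed=0)
    with pytest.raises(ValueError):
        simulate_traits(tree, "Mk", {"q01": -0.1}, seed=0)
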