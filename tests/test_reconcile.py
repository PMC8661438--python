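"""Reconciliation, rates and sweep tests, including the exhaustive
minimum-duplication-loss oracle."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from fishor.reconcile import (branch_rates, collapse_low_support,
                              loss_pseudo_sweep, reconcile, summarize_rates)
from fishor.reconcile.rates import events_table
from fishor.synth import simulate_gene_history, simulate_species_tree
from fishor.treeutils import parse_tree, to_newick


# ------------------------------------------------------------- oracle

def min_dl_oracle(gene_newick: str, species_newick: str) -> int:
    """Exhaustive minimum duplications + losses over all rootings and all
    valid gene-node-to-species-node assignments (independent of the LCA
    shortcut used by the implementation)."""
    sp = parse_tree(species_newick)
    parent = {}
    depth = {}
    nodes = []
    for node in sp.preorder_node_iter():
        nodes.append(node)
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    tip_of = {n.taxon.label: n for n in sp.leaf_node_iter()}

    def ancestors(v):
        out = []
        while v is not None:
            out.append(v)
            v = parent[v]
        return out

    def lca(a, b):
        aa = set(id(x) for x in ancestors(a))
        v = b
        while id(v) not in aa:
            v = parent[v]
        return v

    gt = parse_tree(gene_newick)

    # adjacency of the unrooted gene tree
    adj = {}
    labels = {}
    for node in gt.preorder_node_iter():
        labels[id(node)] = node.taxon.label if node.is_leaf() else None
        for c in node.child_nodes():
            adj.setdefault(id(node), []).append(id(c))
            adj.setdefault(id(c), []).append(id(node))
    root = gt.seed_node
    if len(root.child_nodes()) == 2:
        c1, c2 = root.child_nodes()
        adj[id(c1)] = [x for x in adj[id(c1)] if x != id(root)] + [id(c2)]
        adj[id(c2)] = [x for x in adj[id(c2)] if x != id(root)] + [id(c1)]
        del adj[id(root)]

    edges = set()
    for a, nbrs in adj.items():
        for b in nbrs:
            edges.add(frozenset((a, b)))

    def rooted_topology(a, b):
        def build(nid, come_from):
            kids = [build(x, nid) for x in adj[nid] if x != come_from]
            return (nid, kids)
        return (None, [build(a, b), build(b, a)])

    best = math.inf

    def enumerate_costs(topo):
        """Yield (species assignment, cost) over all valid assignments."""
        nid, kids = topo
        if not kids:
            sp_node = tip_of[labels[nid].split("|")[0]]
            yield sp_node, 0
            return
        for left_node, left_cost in enumerate_costs(kids[0]):
            for right_node, right_cost in enumerate_costs(kids[1]):
                low = lca(left_node, right_node)
                for v in ancestors(low):
                    # a node mapped above the children's LCA, or sharing a
                    # child's mapping, must be a duplication
                    dup = (v is not low) or (v is left_node) or (v is right_node)
                    cost = left_cost + right_cost + (1 if dup else 0)
                    for child_map in (left_node, right_node):
                        d = depth[child_map] - depth[v]
                        cost += d if dup else max(d - 1, 0)
                    yield v, cost

    tips = [n for n in gt.leaf_node_iter()]
    if len(tips) == 1:
        return 0
    for e in edges:
        a, b = tuple(e)
        topo = rooted_topology(a, b)
        for _, cost in enumerate_costs(topo):
            best = min(best, cost)
    return int(best)


def random_instance(seed, max_tips=6):
    rng = np.random.default_rng(seed)
    n_sp = int(rng.integers(2, max_tips + 1))
    sp = simulate_species_tree(n_sp, 100.0, int(rng.integers(1 << 30)))
    species = [l.taxon.label for l in sp.leaf_node_iter()]
    n_genes = int(rng.integers(2, max_tips + 1))
    labels = [f"{species[rng.integers(len(species))]}|g{i}" for i in range(n_genes)]
    # random binary topology by sequential joining
    nodes = [f"{lab}:1.0" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1.0")
    return to_newick(sp), nodes[0] + ";"


@pytest.mark.parametrize("seed", range(40))
def test_reconcile_matches_exhaustive_oracle(seed):
    sp_nwk, g_nwk = random_instance(seed)
    res = reconcile(g_nwk, sp_nwk, reroot=True)
    assert res.duplications + res.losses == min_dl_oracle(g_nwk, sp_nwk)


# ------------------------------------------------------------- collapse


def test_collapse_all_high_support_unchanged():
    t = collapse_low_support("((A:1,B:1)100:1,(C:1,D:1)100:1);", 90)
    assert sum(1 for n in t.preorder_node_iter() if not n.is_leaf()) == 3


def test_collapse_all_zero_gives_star():
    t = collapse_low_support("((A:1,B:1)0:1,(C:1,D:1)0:1);", 90)
    internals = [n for n in t.preorder_node_iter() if not n.is_leaf()]
    assert len(internals) == 1
    assert len(t.seed_node.child_nodes()) == 4


def test_collapse_exactly_one_edge():
    t = collapse_low_support("(((A:1,B:1)89:1,C:1)95:1,(D:1,E:1)95:1);", 90)
    internals = [n for n in t.preorder_node_iter() if not n.is_leaf()]
    assert len(internals) == 3  # one polytomy created


def test_collapse_malformed_support():
    with pytest.raises(ValueError):
        collapse_low_support("((A:1,B:1)high:1,C:1);", 90)


def test_collapse_keeps_tip_set():
    t = collapse_low_support("((A:1,B:1)10:1,(C:1,D:1)95:1);", 90)
    assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B", "C", "D"]


# ------------------------------------------------------------- reconcile basics


def test_congruent_single_copy_no_events():
    res = reconcile("((A|g1:1,B|g2:1):1,C|g3:2);", "((A:1,B:1):1,C:2);")
    assert res.duplications == 0
    assert res.losses == 0
    assert all(ev.n_anc == 1 and ev.n_desc == 1 for ev in res.events.values())


def test_missing_copy_is_one_loss():
    res = reconcile("(A|a:1,B|b:1);", "(A:1,(B:0.5,C:0.5):0.5);")
    assert res.duplications == 0
    assert res.losses == 1
    assert res.events["C"].losses == 1


def test_unmapped_tip_raises():
    with pytest.raises(ValueError):
        reconcile("(A|a:1,Z|z:1);", "(A:1,B:1);")


def test_tip_label_permutation_invariance():
    sp = "((A:1,B:1):1,C:2);"
    g1 = "((A|x:1,A|y:1):1,(B|z:1,C|w:1):1);"
    g2 = "((A|y:1,A|x:1):1,(C|w:1,B|z:1):1);"
    r1 = reconcile(g1, sp)
    r2 = reconcile(g2, sp)
    assert r1.duplications == r2.duplications
    assert r1.losses == r2.losses
    assert {k: (e.gains, e.losses) for k, e in r1.events.items()} \
        == {k: (e.gains, e.losses) for k, e in r2.events.items()}


def test_copy_number_conservation_random_histories():
    tree = simulate_species_tree(8, 150.0, 21)
    for seed in range(6):
        hist = simulate_gene_history(tree, 4, 0.01, 0.01, seed=seed)
        if hist.gene_tree is None or len(hist.gene_tree.leaf_nodes()) < 2:
            continue
        res = reconcile(hist.gene_tree, tree, reroot=False)
        for key, ev in res.events.items():
            assert ev.n_desc >= 0
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            assert res.events[label].n_desc == len(hist.tip_inventory[label])


# ------------------------------------------------------------- rates


def test_branch_rates_arithmetic():
    assert branch_rates(2, 0, 10, 10.0) == pytest.approx((0.02, 0.0))
    assert branch_rates(0, 0, 7, 3.0) == (0.0, 0.0)
    assert branch_rates(3, 6, 20, 15.0) == pytest.approx((0.01, 0.02))


def test_branch_rates_undefined_when_empty():
    b, d = branch_rates(0, 0, 0, 5.0)
    assert math.isnan(b) and math.isnan(d)


def test_branch_rates_invalid_t():
    with pytest.raises(ValueError):
        branch_rates(1, 1, 5, 0.0)


def _table(rows):
    return pd.DataFrame(rows, columns=["branch_id", "t", "n_anc", "gains",
                                       "losses", "b", "d"])


def test_summarize_excludes_short_branches():
    tab = _table([("x", 1.9, 10, 1, 1, 0.01, 0.01),
                  ("y", 1.5, 10, 2, 0, 0.02, 0.0)])
    summary = summarize_rates(tab, 2.0)
    assert summary.empty
    assert set(summary.excluded) == {"x", "y"}


def test_summarize_single_branch():
    tab = _table([("x", 10.0, 10, 1, 2, 0.01, 0.02)])
    s = summarize_rates(tab, 2.0)
    assert s.mean_birth == pytest.approx(0.01)
    assert s.mean_death == pytest.approx(0.02)
    assert s.max_birth == ("x", 0.01)


# ------------------------------------------------------------- sweep


def test_sweep_perfect_correlation():
    rng = np.random.default_rng(3)
    t = rng.uniform(2, 150, size=20)
    losses = rng.integers(0, 30, size=20)
    tab = pd.DataFrame({"t": t, "losses": losses, "n_pseudo": losses,
                        "n_truncated": 0, "n_edge": 0})
    sweep = loss_pseudo_sweep(tab, thresholds=[50, 100, 200])
    defined = sweep.dropna(subset=["r"])
    assert np.allclose(defined["r"], 1.0)


def test_sweep_permutation_null_small_r():
    rng = np.random.default_rng(8)
    n = 200
    tab = pd.DataFrame({"t": rng.uniform(2, 150, size=n),
                        "losses": rng.integers(0, 30, size=n),
                        "n_pseudo": rng.integers(0, 30, size=n),
                        "n_truncated": 0, "n_edge": 0})
    sweep = loss_pseudo_sweep(tab, thresholds=[200])
    assert abs(sweep["r"].iloc[0]) < 3.0 / math.sqrt(n)


def test_sweep_undefined_below_three_branches():
    tab = pd.DataFrame({"t": [5.0, 50.0, 90.0], "losses": [1, 2, 3],
                        "n_pseudo": [1, 2, 3], "n_truncated": 0, "n_edge": 0})
    sweep = loss_pseudo_sweep(tab, thresholds=[6, 100])
    assert math.isnan(sweep.loc[sweep.threshold == 6, "r"].iloc[0])
    assert not math.isnan(sweep.loc[sweep.threshold == 100, "r"].iloc[0])


def test_sweep_requires_three_rows():
    tab = pd.DataFrame({"t": [5.0], "losses": [1], "n_pseudo": [1],
                        "n_truncated": 0, "n_edge": 0})
    with pytest.raises(ValueError):
        loss_pseudo_sweep(tab)


def test_sweep_variant_selectors():
    tab = pd.DataFrame({"t": [10.0, 20, 30, 40], "losses": [1, 2, 3, 4],
                        "n_pseudo": [1, 2, 3, 4], "n_truncated": [4, 3, 2, 1],
                        "n_edge": [0, 0, 0, 0]})
    r_pseudo = loss_pseudo_sweep(tab, thresholds=[50], variant="pseudo")["r"].iloc[0]
    r_trunc = loss_pseudo_sweep(tab, thresholds=[50], variant="truncated")["r"].iloc[0]
    assert r_pseudo == pytest.approx(1.0)
    assert r_trunc == pytest.approx(-1.0)
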