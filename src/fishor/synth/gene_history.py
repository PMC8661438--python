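"""Gene-family histories: per-branch birth-death simulation on a species tree.

Each species-tree branch carries a Gillespie simulation of per-gene
duplication (birth) and loss (death). The event ledger satisfies
``n_desc = n_anc + G - L`` on every branch, and the true gene tree
relating all extant copies is returned with tips named ``species|gene``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class _GNode:
    __slots__ = ("birth_time", "children", "label", "end_time")

    def __init__(self, birth_time: float):
        self.birth_time = birth_time
        self.children: list["_GNode"] = []
        self.label: str | None = None
        self.end_time: float | None = None


@dataclass
class BranchLedger:
    """Per-species-branch event record (branch keyed by its child node)."""

    branch_id: str
    t: float
    n_anc: int
    gains: int
    losses: int

    @property
    def n_desc(self) -> int:
        return self.n_anc + self.gains - self.losses


@dataclass
class GeneFamilyHistory:
    """Ground-truth record of one simulated gene family."""

    species_tree: dendropy.Tree
    branches: dict[str, BranchLedger]
    tip_inventory: dict[str, list[str]]
    gene_tree: dendropy.Tree | None
    n_root: int

    @property
    def n_extant(self) -> int:
        return sum(len(v) for v in self.tip_inventory.values())


def _branch_key(node: dendropy.Node, fallback: int) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{fallback}"


def simulate_gene_history(tree: dendropy.Tree, n_root: int, birth: float,
                          death: float, seed: int) -> GeneFamilyHistory:
    """Simulate gains and losses of gene copies along a species tree.

    ``birth`` and ``death`` are per-gene per-Myr rates. Returns the
    per-branch gain/loss ledger, the extant inventory per species tip, and
    the true gene tree (None if the family went extinct).
    """
    if birth < 0 or death < 0:
        raise ValueError("rates must be non-negative")
    if n_root < 0:
        raise ValueError("n_root must be non-negative")
    rng = np.random.default_rng(seed)
    total = birth + death

    # Ensure internal nodes have stable ids for the ledger.
    for i, node in enumerate(tree.preorder_node_iter()):
        if not node.is_leaf() and not node.label:
            node.label = f"node{i}"

    depths: dict = {}
    for node in tree.preorder_node_iter():
        depths[node] = (0.0 if node.parent_node is None
                        else depths[node.parent_node] + (node.edge.length or 0.0))

    gene_root = _GNode(0.0)
    root_lineages = [gene_root] if n_root == 1 else []
    if n_root > 1:
        # polytomy of n_root initial copies at the species root
        for _ in range(n_root):
            child = _GNode(0.0)
            gene_root.children.append(child)
            root_lineages.append(child)
    branches: dict[str, BranchLedger] = {}
    tip_inventory: dict[str, list[str]] = {}
    counter = [0]

    def simulate_branch(lineages: list[_GNode], t0: float, t1: float):
        gains = 0
        losses = 0
        t = t0
        live = list(lineages)
        while live and total > 0:
            rate = len(live) * total
            dt = rng.exponential(1.0 / rate)
            if t + dt > t1:
                break
            t += dt
            idx = int(rng.integers(len(live)))
            node = live[idx]
            node.end_time = t
            if rng.random() < (birth / total if total else 0.0):
                gains += 1
                c1, c2 = _GNode(t), _GNode(t)
                node.children = [c1, c2]
                live[idx] = c1
                live.append(c2)
            else:
                losses += 1
                live.pop(idx)
        return live, gains, losses

    def recurse(species_node: dendropy.Node, lineages: list[_GNode], idx: int):
        t0 = depths.get(species_node.parent_node, 0.0)
        t1 = depths[species_node]
        live, gains, losses = simulate_branch(lineages, t0, t1)
        key = _branch_key(species_node, idx)
        branches[key] = BranchLedger(branch_id=key, t=t1 - t0,
                                     n_anc=len(lineages), gains=gains, losses=losses)
        if species_node.is_leaf():
            label = species_node.taxon.label
            names = []
            for node in live:
                counter[0] += 1
                gid = f"g{counter[0]}"
                node.end_time = t1
                node.label = f"{label}|{gid}"
                names.append(gid)
            tip_inventory[label] = names
        else:
            for child in species_node.child_nodes():
                branch_copies = []
                for node in live:
                    node.end_time = t1
                    sub = _GNode(t1)
                    node.children.append(sub)
                    branch_copies.append(sub)
                recurse(child, branch_copies, idx)

    root = tree.seed_node
    for child in root.child_nodes():
        branch_copies = []
        for node in root_lineages:
            sub = _GNode(0.0)
            node.children.append(sub)
            branch_copies.append(sub)
        recurse(child, branch_copies, id(child) % 10_000)

    gene_tree = _to_dendropy(gene_root)
    return GeneFamilyHistory(species_tree=tree, branches=branches,
                             tip_inventory=tip_inventory, gene_tree=gene_tree,
                             n_root=n_root)


def _prune_dead(node: _GNode) -> _GNode | None:
    """Keep only lineages with extant (labeled) descendants; suppress
    unifurcations, accumulating time into birth_time spans."""
    if not node.children:
        return node if node.label is not None else None
    kept = []
    for child in node.children:
        pruned = _prune_dead(child)
        if pruned is not None:
            kept.append(pruned)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.birth_time = node.birth_time
        return child
    node.children = kept
    return node


def _to_dendropy(gene_root: _GNode) -> dendropy.Tree | None:
    pruned = _prune_dead(gene_root)
    if pruned is None:
        return None
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: _GNode, dparent):
        dnode = dendropy.Node()
        end = node.end_time if node.end_time is not None else node.birth_time
        dnode.edge.length = max(end - node.birth_time, 0.0)
        if not node.children:
            dnode.taxon = taxa.require_taxon(label=node.label)
        dparent.add_child(dnode)
        for child in node.children:
            build(child, dnode)

    if not pruned.children:  # single surviving copy
        build(pruned, tree.seed_node)
    else:
        for child in pruned.children:
            build(child, tree.seed_node)
    tree.is_rooted = True
    return tree
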