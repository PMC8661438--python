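"""Ultrametric species-tree simulation (pure-birth conditioned on size)."""

from __future__ import annotations

import dendropy
import numpy as np


class _Node:
    __slots__ = ("birth_time", "children", "label", "end_time")

    def __init__(self, birth_time: float):
        self.birth_time = birth_time
        self.children: list["_Node"] = []
        self.label: str | None = None
        self.end_time: float | None = None


def simulate_species_tree(n_taxa: int, crown_age: float, seed: int) -> dendropy.Tree:
    """Simulate a rooted, ultrametric, binary Yule tree.

    A pure-birth process starting from two crown lineages runs until
    ``n_taxa`` lineages exist; one further exponential waiting time is
    appended and node ages are rescaled so the root-to-tip depth equals
    ``crown_age`` exactly. Deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    rng = np.random.default_rng(seed)
    root = _Node(0.0)
    left, right = _Node(0.0), _Node(0.0)
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.end_time = t
        c1, c2 = _Node(t), _Node(t)
        parent.children = [c1, c2]
        active.extend([c1, c2])
    t += rng.exponential(1.0 / len(active))
    present = t
    width = max(1, len(str(n_taxa)))
    for i, node in enumerate(sorted(active, key=lambda nd: nd.birth_time)):
        node.end_time = present
        node.label = f"sp{i + 1:0{width}d}"
    scale = crown_age / present

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: _Node, parent_dnode):
        dnode = dendropy.Node()
        end = node.end_time if node.end_time is not None else present
        dnode.edge.length = (end - node.birth_time) * scale
        if not node.children:
            dnode.taxon = taxa.require_taxon(label=node.label)
        parent_dnode.add_child(dnode)
        for child in node.children:
            build(child, dnode)

    tree.seed_node.edge.length = None
    for child in root.children:
        build(child, tree.seed_node)
    tree.is_rooted = True
    return tree
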