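"""Duplication-loss reconciliation of a gene tree with a species tree.

Parsimony LCA-mapping reconciliation with optional DL-minimizing rooting
and duplication-minimizing greedy resolution of gene-tree polytomies.
Per-species-branch gains (duplications) and losses are reported together
with reconstructed copy numbers at every species node; branches are keyed
by their child node (tip label or internal-node label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from fishor.treeutils import parse_tree


# ---------------------------------------------------------------------------
# species-tree indexing


class SpeciesIndex:
    """Parent/depth tables and LCA queries over a rooted species tree."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = parse_tree(tree)
        self.nodes: list[dendropy.Node] = []
        self.parent: dict = {}
        self.depth: dict = {}
        self.key: dict = {}
        self.by_label: dict = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            self.nodes.append(node)
            par = node.parent_node
            self.parent[node] = par
            self.depth[node] = 0 if par is None else self.depth[par] + 1
            if node.is_leaf():
                key = node.taxon.label
            else:
                key = node.label or f"node{i}"
                node.label = key
            self.key[node] = key
            self.by_label[key] = node
        self.root = self.tree.seed_node

    def lca(self, a, b):
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def branch_length(self, node) -> float:
        return node.edge.length if node.edge.length is not None else 0.0


# ---------------------------------------------------------------------------
# gene-tree structure


class GNode:
    __slots__ = ("children", "label", "mapping", "is_dup", "length")

    def __init__(self, label=None, length=0.0):
        self.children: list["GNode"] = []
        self.label = label
        self.mapping = None
        self.is_dup = False
        self.length = length

    def is_leaf(self):
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def default_species_map(tip_label: str) -> str:
    """Map gene-tree tip names ``species|gene`` to the species label."""
    return tip_label.split("|")[0]


def _from_dendropy(tree: dendropy.Tree) -> GNode:
    def conv(node):
        g = GNode(label=node.taxon.label if node.is_leaf() else node.label,
                  length=node.edge.length or 0.0)
        for c in node.child_nodes():
            g.children.append(conv(c))
        return g

    return conv(tree.seed_node)


# ---------------------------------------------------------------------------
# rooting


def _unrooted_edges(root: GNode):
    """Adjacency view of the gene tree with the root suppressed."""
    adj: dict[int, list[tuple[GNode, float]]] = {}
    nodes: dict[int, GNode] = {}

    def add(a: GNode, b: GNode, length: float):
        adj.setdefault(id(a), []).append((b, length))
        adj.setdefault(id(b), []).append((a, length))
        nodes[id(a)] = a
        nodes[id(b)] = b

    def walk(node: GNode):
        for c in node.children:
            add(node, c, c.length)
            walk(c)

    walk(root)
    # suppress a degree-2 root: connect its two children directly
    if len(root.children) == 2:
        c1, c2 = root.children
        adj[id(c1)] = [(n, l) for n, l in adj[id(c1)] if n is not root]
        adj[id(c2)] = [(n, l) for n, l in adj[id(c2)] if n is not root]
        joint = c1.length + c2.length
        adj[id(c1)].append((c2, joint))
        adj[id(c2)].append((c1, joint))
        del adj[id(root)]
        del nodes[id(root)]
    edges = set()
    edge_list = []
    for nid, nbrs in adj.items():
        for nbr, length in nbrs:
            key = frozenset((nid, id(nbr)))
            if key not in edges:
                edges.add(key)
                edge_list.append((nodes[nid], nbr, length))
    return adj, edge_list


def _root_at_edge(adj, a: GNode, b: GNode, length: float) -> GNode:
    """Rooted copy of the unrooted tree with the root on edge (a, b)."""

    def build(node: GNode, come_from: GNode, up_len: float) -> GNode:
        g = GNode(label=node.label, length=up_len)
        g.mapping = node.mapping if node.is_leaf() else None
        for nbr, l in adj[id(node)]:
            if nbr is come_from:
                continue
            g.children.append(build(nbr, node, l))
        return g

    root = GNode()
    root.children = [build(a, b, length / 2.0), build(b, a, length / 2.0)]
    return root


def _height(node: GNode) -> float:
    if node.is_leaf():
        return 0.0
    return max(c.length + _height(c) for c in node.children)


# ---------------------------------------------------------------------------
# polytomy resolution and LCA reconciliation


def _map_leaves(root: GNode, spec: SpeciesIndex, species_map) -> None:
    for leaf in root.leaves():
        sp = species_map(leaf.label)
        if sp not in spec.by_label:
            raise ValueError(f"gene-tree tip {leaf.label!r} maps to unknown "
                             f"species {sp!r}")
        leaf.mapping = spec.by_label[sp]


def _resolve_and_map(node: GNode, spec: SpeciesIndex) -> None:
    """Post-order LCA mapping; polytomies are refined greedily by joining
    the pair of children with the deepest joint mapping, which minimizes
    the duplications created by the refinement."""
    for c in node.children:
        _resolve_and_map(c, spec)
    if node.is_leaf():
        return
    node.children.sort(key=lambda c: min(l.label for l in c.leaves()))
    while len(node.children) > 2:
        best = None
        for i in range(len(node.children)):
            for j in range(i + 1, len(node.children)):
                anc = spec.lca(node.children[i].mapping, node.children[j].mapping)
                d = spec.depth[anc]
                if best is None or d > best[0]:
                    best = (d, i, j)
        _, i, j = best
        joint = GNode()
        joint.children = [node.children[i], node.children[j]]
        joint.mapping = spec.lca(joint.children[0].mapping, joint.children[1].mapping)
        joint.is_dup = any(c.mapping is joint.mapping for c in joint.children)
        node.children = [c for k, c in enumerate(node.children) if k not in (i, j)]
        node.children.append(joint)
        node.children.sort(key=lambda c: min(l.label for l in c.leaves()))
    m = node.children[0].mapping
    for c in node.children[1:]:
        m = spec.lca(m, c.mapping)
    node.mapping = m
    node.is_dup = any(c.mapping is node.mapping for c in node.children)


def _count_events(root: GNode, spec: SpeciesIndex):
    """Per-branch duplication and loss tallies from an LCA-mapped tree."""
    gains: dict = {}
    losses: dict = {}

    def add(d: dict, node, k: int = 1):
        d[node] = d.get(node, 0) + k

    def walk(g: GNode):
        if g.is_dup:
            add(gains, g.mapping)
        for c in g.children:
            # losses along the species path from g.mapping down to c.mapping
            chain = []
            v = c.mapping
            while v is not g.mapping:
                chain.append(v)
                v = spec.parent[v]
            # chain = [M(c), ..., child-of-M(g)]; nodes above M(c) lose the
            # lineage in their off-path children. A duplication also loses
            # it in the off-path children of M(g) itself.
            for idx, v in enumerate(chain[1:], start=1):
                below = chain[idx - 1]
                for child in v.child_nodes():
                    if child is not below:
                        add(losses, child)
            if g.is_dup and chain:
                below = chain[-1]
                for child in g.mapping.child_nodes():
                    if child is not below:
                        add(losses, child)
        for c in g.children:
            walk(c)

    walk(root)
    return gains, losses


def _dl_cost(root: GNode, spec: SpeciesIndex) -> tuple[int, int]:
    gains, losses = _count_events(root, spec)
    return sum(gains.values()), sum(losses.values())


# ---------------------------------------------------------------------------
# public API


@dataclass
class BranchEvents:
    """Events on one species-tree branch (keyed by its child node)."""

    branch_id: str
    t: float
    n_anc: float
    gains: int
    losses: int

    @property
    def n_desc(self) -> float:
        return self.n_anc + self.gains - self.losses


@dataclass
class ReconciliationResult:
    species_tree: dendropy.Tree
    events: dict[str, BranchEvents]
    duplications: int
    losses: int
    gene_root_species: str
    node_counts: dict[str, float] = field(default_factory=dict)


def reconcile(gene_tree, species_tree, species_map=default_species_map,
              reroot: bool = True) -> ReconciliationResult:
    """LCA-mapping duplication-loss reconciliation.

    When ``reroot`` is true every rooting of the gene tree is evaluated
    and the one minimizing duplications + losses is chosen (ties broken by
    the rooting closest to the midpoint). Gene-tree polytomies are
    resolved to minimize duplications before mapping.
    """
    spec = SpeciesIndex(species_tree)
    gtree = parse_tree(gene_tree)
    groot = _from_dendropy(gtree)
    leaves = groot.leaves()
    if not leaves or (len(leaves) == 1 and leaves[0].label is None):
        raise ValueError("gene tree has no tips")
    _map_leaves(groot, spec, species_map)

    if reroot and len(leaves) > 2:
        adj, edges = _unrooted_edges(groot)
        best = None
        for a, b, length in edges:
            cand = _root_at_edge(adj, a, b, length)
            _resolve_and_map(cand, spec)
            dups, loss = _dl_cost(cand, spec)
            imbalance = abs((_height(cand.children[0]) + cand.children[0].length)
                            - (_height(cand.children[1]) + cand.children[1].length))
            key = (dups + loss, imbalance)
            if best is None or key < best[0]:
                best = (key, cand, dups, loss)
        _, groot, dups, loss = best
    else:
        _resolve_and_map(groot, spec)
        dups, loss = _dl_cost(groot, spec)

    gains, losses = _count_events(groot, spec)

    # copy numbers by conservation below the gene root's mapping
    m_root = groot.mapping
    node_n: dict = {}
    events: dict[str, BranchEvents] = {}
    for node in spec.tree.preorder_node_iter():
        key = spec.key[node]
        t = spec.branch_length(node)
        g = gains.get(node, 0)
        l = losses.get(node, 0)
        par = spec.parent[node]
        if node is m_root:
            n_anc = 1.0
        elif par in node_n and node_n[par] is not None and _is_descendant(node, m_root, spec):
            n_anc = node_n[par]
        else:
            n_anc = None
        if n_anc is None:
            node_n[node] = None
            if g or l:
                raise AssertionError("events outside the gene root subtree")
            events[key] = BranchEvents(branch_id=key, t=t, n_anc=0.0, gains=0, losses=0)
        else:
            events[key] = BranchEvents(branch_id=key, t=t, n_anc=n_anc,
                                       gains=g, losses=l)
            node_n[node] = n_anc + g - l
            if node_n[node] < 0:
                raise AssertionError("negative copy number in reconciliation")
    counts = {spec.key[n]: (v if v is not None else 0.0) for n, v in node_n.items()}
    return ReconciliationResult(species_tree=spec.tree, events=events,
                                duplications=dups, losses=loss,
                                gene_root_species=spec.key[m_root],
                                node_counts=counts)


def _is_descendant(node, ancestor, spec: SpeciesIndex) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = spec.parent[node]
    return False
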