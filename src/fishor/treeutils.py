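"""Shared helpers for dendropy trees: covariance matrices, depths, parsing."""

from __future__ import annotations

import io

import dendropy
import numpy as np


def parse_tree(source) -> dendropy.Tree:
    """Read a rooted tree from a Newick string, path, or pass through."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" not in text:  # a path
        with open(text) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict:
    """Distance from the root to every node (root depth 0)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def vcv_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance: C[i, j] = shared root-to-MRCA path length.

    Returns (C, taxa) with rows ordered by ``taxa`` (default: tree order).
    """
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if taxa is None:
        taxa = labels
    index = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for lf in leaves:
        i = index[lf.taxon.label]
        C[i, i] = depths[lf]
    # For each internal node, pairs of tips in different child subtrees share it.
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node.taxon.label]]
        else:
            children = [tipsets[c] for c in node.child_nodes()]
            merged = []
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for x in children[a]:
                        for y in children[b]:
                            C[x, y] = depths[node]
                            C[y, x] = depths[node]
            for c in children:
                merged.extend(c)
            tipsets[node] = merged
    return C, list(taxa)


def patristic_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Pairwise path-length distances between tips."""
    C, taxa = vcv_matrix(tree, taxa)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C, taxa


def to_newick(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip()
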