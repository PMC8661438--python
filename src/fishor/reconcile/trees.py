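"""Gene-tree preprocessing: support-based polytomy collapse."""

from __future__ import annotations

import dendropy

from fishor.treeutils import parse_tree


def _support_of(node: dendropy.Node):
    """Internal-node support parsed from the node label (absent -> None)."""
    label = node.label
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError as exc:
        raise ValueError(f"malformed support value {label!r}") from exc


def collapse_low_support(tree, threshold: float = 90.0) -> dendropy.Tree:
    """Contract every internal edge whose support is below ``threshold``.

    Nodes without a support label are kept. The tip set is unchanged;
    contracted edges produce polytomies. Returns a new tree.
    """
    tree = parse_tree(tree).clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = _support_of(node)
        if support is not None and not (0 <= support <= 100):
            raise ValueError(f"support {support} outside [0, 100]")
        if support is not None and support < threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return tree
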