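"""Fitch parsimony for a binary character: DOWNPASS, ACCTRAN, DELTRAN.

State sets are computed by a 0/1-cost Sankoff dynamic program (valid for
polytomies as well as binary nodes). DOWNPASS returns the full set of
most-parsimonious states per node; ACCTRAN resolves ambiguity by placing
changes as close to the root as possible, DELTRAN as close to the tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from fishor.treeutils import parse_tree

INF = 10 ** 9
UNKNOWN = frozenset({0, 1})


def binarize_lamellae(count) -> int | None:
    """Rosette presence from the primary-lamella count: >=3 -> 1, 0-2 -> 0,
    unknown (None) -> None."""
    if count is None:
        return None
    count = int(count)
    if count < 0:
        raise ValueError("lamella count must be non-negative")
    return 1 if count >= 3 else 0


@dataclass
class Reconstruction:
    method: str
    node_states: dict[str, frozenset] = field(default_factory=dict)
    node_posteriors: dict[str, tuple[float, float]] = field(default_factory=dict)
    changes: int | None = None
    log_likelihood: float | None = None
    params: dict = field(default_factory=dict)


def _node_key(node: dendropy.Node, index: int) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    node.label = f"node{index}"
    return node.label


def _tip_cost(state, trait_map, label: str):
    if label not in trait_map:
        raise ValueError(f"tip {label!r} missing from the trait map")
    observed = trait_map[label]
    if observed is None or observed == "unknown":
        return 0
    return 0 if int(observed) == state else INF


def parsimony_reconstruct(tree, trait_map: dict, method: str = "DOWNPASS"
                          ) -> Reconstruction:
    """Fitch-style reconstruction of a binary character.

    ``trait_map`` maps tip label -> 0 | 1 | None (unknown = any state).
    ``method``: DOWNPASS (most-parsimonious state sets), ACCTRAN or
    DELTRAN. The minimum change count is identical across methods.
    """
    method = method.upper()
    if method not in ("DOWNPASS", "ACCTRAN", "DELTRAN"):
        raise ValueError(f"unknown parsimony method {method!r}")
    tree = parse_tree(tree).clone(depth=1)
    keys: dict = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = _node_key(node, i)

    # bottom-up minimal cost per (node, state)
    down: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = [_tip_cost(s, trait_map, keys[node]) for s in (0, 1)]
        else:
            costs = []
            for s in (0, 1):
                c = 0
                for child in node.child_nodes():
                    c += min(down[child][t] + (0 if t == s else 1) for t in (0, 1))
                costs.append(c)
            down[node] = costs

    root = tree.seed_node
    total = min(down[root])

    # top-down minimal cost of the rest of the tree per (node, state)
    up: dict = {root: [0, 0]}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            vals = []
            for s in (0, 1):
                best = INF
                for ps in (0, 1):
                    c = up[node][ps] + (0 if ps == s else 1)
                    for sib in node.child_nodes():
                        if sib is child:
                            continue
                        c += min(down[sib][t] + (0 if t == ps else 1) for t in (0, 1))
                    best = min(best, c)
                vals.append(best)
            up[child] = vals

    # most-parsimonious state sets (states achievable in some MP labeling)
    mpr: dict = {}
    for node in tree.preorder_node_iter():
        mpr[node] = frozenset(s for s in (0, 1)
                              if down[node][s] + up[node][s] == total)

    # Fitch downpass sets (first-pass preliminary sets) for ACCTRAN
    fitch: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            observed = trait_map[keys[node]]
            fitch[node] = (UNKNOWN if observed is None or observed == "unknown"
                           else frozenset({int(observed)}))
        else:
            sets = [fitch[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            fitch[node] = inter if inter else frozenset.union(*sets)

    if method == "DOWNPASS":
        final = mpr
    else:
        base = fitch if method == "ACCTRAN" else mpr
        final = {}
        final[root] = base[root] if method == "ACCTRAN" else mpr[root]
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            parent_states = final[node.parent_node]
            inter = base[node] & parent_states
            final[node] = inter if inter else base[node]

    changes = total if total < INF else None
    if changes is None:
        raise ValueError("conflicting fixed tip states (infinite cost)")
    return Reconstruction(method=method,
                          node_states={keys[n]: final[n]
                                       for n in tree.preorder_node_iter()},
                          changes=changes)
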