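"""Two-state maximum-likelihood ancestral reconstruction (F81-type CTMC).

The binary character evolves under a CTMC with stationary frequencies
(pi0, pi1) and a rate scaler, the two-state analogue of the F81 model:
P(i -> j, t) = pi_j + (delta_ij - pi_j) * exp(-s * t). Frequencies and the
scaler are ML-estimated by bounded optimization; marginal posteriors per
node come from the standard up/down pruning passes. MAP picks the best
state; MPPA keeps both states when their posteriors tie.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import minimize

from fishor.asr.parsimony import Reconstruction, _node_key
from fishor.treeutils import parse_tree

_EPS_BRANCH = 1e-8


def _transition_matrix(pi1: float, scale: float, t: float) -> np.ndarray:
    e = math.exp(-scale * t)
    pi = np.array([1.0 - pi1, pi1])
    P = np.tile(pi, (2, 1)) * (1.0 - e)
    P[0, 0] += e
    P[1, 1] += e
    return P


def _tip_partial(observed) -> np.ndarray:
    if observed is None or observed == "unknown":
        return np.ones(2)
    vec = np.zeros(2)
    vec[int(observed)] = 1.0
    return vec


def _prepare(tree, trait_map):
    tree = parse_tree(tree).clone(depth=1)
    keys = {}
    fixed = False
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = _node_key(node, i)
        if node.parent_node is not None and (node.edge.length or 0.0) <= 0:
            node.edge.length = _EPS_BRANCH
            fixed = True
    if fixed:
        warnings.warn("zero-length branches replaced by epsilon", stacklevel=3)
    for leaf in tree.leaf_node_iter():
        if keys[leaf] not in trait_map:
            raise ValueError(f"tip {keys[leaf]!r} missing from the trait map")
    return tree, keys


def _log_likelihood(tree, keys, trait_map, pi1: float, scale: float,
                    return_partials: bool = False):
    up = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[node] = _tip_partial(trait_map[keys[node]])
        else:
            part = np.ones(2)
            for child in node.child_nodes():
                P = _transition_matrix(pi1, scale, child.edge.length)
                part = part * (P @ up[child])
            up[node] = part
    pi = np.array([1.0 - pi1, pi1])
    lik = float(pi @ up[tree.seed_node])
    if lik <= 0:
        return (-math.inf, up) if return_partials else -math.inf
    return (math.log(lik), up) if return_partials else math.log(lik)


def _posteriors(tree, keys, trait_map, pi1: float, scale: float):
    logL, up = _log_likelihood(tree, keys, trait_map, pi1, scale,
                               return_partials=True)
    pi = np.array([1.0 - pi1, pi1])
    down = {tree.seed_node: pi.copy()}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            P = _transition_matrix(pi1, scale, child.edge.length)
            other = down[node].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                Ps = _transition_matrix(pi1, scale, sib.edge.length)
                other = other * (Ps @ up[sib])
            down[child] = other @ P
    post = {}
    for node in tree.preorder_node_iter():
        w = up[node] * down[node]
        total = w.sum()
        post[keys[node]] = tuple(w / total) if total > 0 else (0.5, 0.5)
    return logL, post


def ml_reconstruct(tree, trait_map: dict, method: str = "ML-MAP",
                   n_restarts: int = 5, seed: int = 0) -> Reconstruction:
    """ML marginal reconstruction of a binary character.

    ``method`` is ML-MAP (single best state per node) or ML-MPPA (keep
    every state whose posterior ties the maximum). Stationary frequency
    and rate scaler are estimated by L-BFGS-B with random restarts.
    """
    method = method.upper()
    if method not in ("ML-MAP", "ML-MPPA"):
        raise ValueError(f"unknown ML method {method!r}")
    tree, keys = _prepare(tree, trait_map)

    def objective(x):
        pi1 = 1.0 / (1.0 + math.exp(-x[0]))
        scale = math.exp(x[1])
        return -_log_likelihood(tree, keys, trait_map, pi1, scale)

    rng = np.random.default_rng(seed)
    from fishor.treeutils import node_depths

    depths = node_depths(tree)
    depth = max((depths[leaf] for leaf in tree.leaf_node_iter()), default=1.0) or 1.0
    best = None
    starts = [(0.0, math.log(1.0 / max(depth, 1e-6)))]
    starts += [(float(rng.normal(0, 1.5)),
                float(rng.normal(math.log(1.0 / max(depth, 1e-6)), 1.5)))
               for _ in range(n_restarts - 1)]
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=[(-8, 8), (-18, 8)], options={"ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    pi1 = 1.0 / (1.0 + math.exp(-best.x[0]))
    scale = math.exp(best.x[1])
    logL, post = _posteriors(tree, keys, trait_map, pi1, scale)

    states = {}
    for key, (p0, p1) in post.items():
        if method == "ML-MAP":
            states[key] = frozenset({0 if p0 >= p1 else 1})
        else:  # MPPA: keep the smallest set maximizing expected accuracy
            if abs(p0 - p1) < 1e-9:
                states[key] = frozenset({0, 1})
            else:
                states[key] = frozenset({0 if p0 > p1 else 1})
    return Reconstruction(method=method, node_states=states,
                          node_posteriors=post, log_likelihood=logL,
                          params={"pi1": pi1, "scale": scale})
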