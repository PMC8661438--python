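"""Trait simulation on a species tree: BM, OU, Pagel-lambda, binary Mk."""

from __future__ import annotations

import numpy as np

from fishor.treeutils import node_depths, patristic_matrix, vcv_matrix


def simulate_traits(tree, model: str = "BM", params: dict | None = None,
                    seed: int = 0) -> dict[str, float | int]:
    """Simulate one trait column on the tips of ``tree``.

    Models
    ------
    ``BM``      params: sigma2 (>0 unless exactly 0), root (default 0)
    ``OU``      params: sigma2, alpha (>= 0), root/optimum (default 0)
    ``lambda``  params: sigma2, lam in [0, 1], root
    ``Mk``      params: q01, q10 (>= 0), root_state in {0, 1}

    Continuous traits are drawn from the multivariate normal implied by
    the model on the tree; binary traits by CTMC simulation along
    branches. Deterministic given ``seed``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    model = model.upper()
    if model in ("BM", "LAMBDA", "OU"):
        sigma2 = params.get("sigma2", 1.0)
        root = params.get("root", 0.0)
        if sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if model == "OU":
            alpha = params.get("alpha", 0.0)
            if alpha < 0:
                raise ValueError("OU alpha must be >= 0")
            if alpha == 0:
                V, taxa = vcv_matrix(tree)
                V = sigma2 * V
            else:
                D, taxa = patristic_matrix(tree)
                V = sigma2 / (2 * alpha) * np.exp(-alpha * D)
        else:
            C, taxa = vcv_matrix(tree)
            if model == "LAMBDA":
                lam = params.get("lam", 1.0)
                if not (0 <= lam <= 1):
                    raise ValueError("lambda must lie in [0, 1]")
                V = lam * C + np.diag((1 - lam) * np.diag(C))
            else:
                V = C
            V = sigma2 * V
        if sigma2 == 0:
            return {t: float(root) for t in taxa}
        values = rng.multivariate_normal(np.full(len(taxa), root), V, method="svd")
        return {t: float(v) for t, v in zip(taxa, values)}
    if model in ("MK", "MK-BINARY"):
        q01 = params.get("q01", 1.0)
        q10 = params.get("q10", 1.0)
        if q01 < 0 or q10 < 0:
            raise ValueError("Mk rates must be >= 0")
        root_state = int(params.get("root_state", 0))
        if root_state not in (0, 1):
            raise ValueError("root_state must be 0 or 1")
        states = {tree.seed_node: root_state}
        out = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            state = states[node.parent_node]
            t = node.edge.length or 0.0
            # exact two-state CTMC transition probability
            q = q01 + q10
            if q > 0 and t > 0:
                p1 = q01 / q + ((1 - q01 / q) if state == 1 else -q01 / q) * np.exp(-q * t)
                state = int(rng.random() < p1)
            states[node] = state
            if node.is_leaf():
                out[node.taxon.label] = state
        return out
    raise ValueError(f"unknown trait model {model!r}")
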