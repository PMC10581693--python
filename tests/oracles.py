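"""Independent oracles used to cross-check the implementation.

Everything here is deliberately naive -- exhaustive enumeration, generic
numerical optimisation, textbook formulas -- and shares no code with the
package internals it validates.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import optimize

from splicemap.phylo import PhyloNode, PhyloTree


def random_tree(rng: np.random.Generator, n_leaves: int, polytomies: bool = True) -> PhyloTree:
    """Random rooted tree with random branch lengths in [0.1, 2]."""
    nodes = [
        PhyloNode(label=f"L{i}", branch_length=float(np.round(rng.uniform(0.1, 2), 3)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        k = 2
        if polytomies and len(nodes) > 2 and rng.random() < 0.2:
            k = 3
        picks = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(k)]
        parent = PhyloNode(branch_length=float(np.round(rng.uniform(0.1, 2), 3)))
        for child in picks:
            child.parent = parent
            parent.children.append(child)
        nodes.append(parent)
    root = nodes[0]
    root.branch_length = 0.0
    return PhyloTree(root)


def brute_force_dollo(tree: PhyloTree, presence: dict[str, int]) -> int:
    """Minimum losses over all single-gain irreversible-loss histories.

    Enumerates every 0/1 assignment to internal nodes; a history is valid
    when the total number of gains (a root state of 1, or a 0->1 edge) is
    exactly one; its cost is the number of 1->0 edges.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for bits in product((0, 1), repeat=len(internals)):
        state = dict(zip(internals, bits))
        for leaf in tree.leaves:
            state[leaf] = presence.get(leaf.label, 0)
        gains = state[tree.root]
        losses = 0
        for node in tree.preorder():
            if node is tree.root:
                continue
            s_p, s_c = state[node.parent], state[node]
            gains += (1 - s_p) * s_c
            losses += s_p * (1 - s_c)
        if gains == 1 and (best is None or losses < best):
            best = losses
    return best


def brute_force_sankoff(
    tree: PhyloTree, leaf_state_idx: dict[str, int], cost_matrix: np.ndarray
) -> float:
    """Minimum total parsimony cost by enumerating internal assignments."""
    S = cost_matrix.shape[0]
    internals = [n for n in tree.postorder() if not n.is_leaf]
    axis = {n: i for i, n in enumerate(internals)}
    shape = (S,) * len(internals)
    total = np.zeros(shape)

    def along(vec, ax):
        idx = [None] * len(internals)
        idx[ax] = slice(None)
        return vec[tuple(idx)]

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_ax = axis[node.parent]
        if node.is_leaf:
            total = total + along(cost_matrix[:, leaf_state_idx[node.label]], parent_ax)
        else:
            child_ax = axis[node]
            # place the (parent, child) cost matrix on the right axes
            view = cost_matrix if parent_ax < child_ax else cost_matrix.T
            sh = [1] * len(internals)
            sh[parent_ax] = S
            sh[child_ax] = S
            total = total + view.reshape(sh)
    return float(total.min())


def numeric_bm_estimates(tree: PhyloTree, tip_values: dict[str, float]) -> dict:
    """Joint-ML internal states by generic numerical optimisation.

    For any Brownian rate the joint likelihood over internal states is
    maximised by minimising sum((x_parent - x_child)^2 / branch_length);
    this minimises it with BFGS from a cold start.
    """
    internals = [n for n in tree.preorder() if not n.is_leaf]
    pos = {n: i for i, n in enumerate(internals)}

    def objective(x):
        val = 0.0
        for node in tree.preorder():
            if node is tree.root:
                continue
            xv = tip_values[node.label] if node.is_leaf else x[pos[node]]
            pv = x[pos[node.parent]]
            val += (pv - xv) ** 2 / max(node.branch_length, 1e-12)
        return val

    res = optimize.minimize(
        objective,
        np.zeros(len(internals)),
        method="BFGS",
        options={"gtol": 1e-14, "maxiter": 10_000},
    )
    return {n: float(res.x[pos[n]]) for n in internals}


def ols_fit(y: np.ndarray, X: np.ndarray):
    """Textbook OLS coefficients and standard errors via lstsq."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), sigma2
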