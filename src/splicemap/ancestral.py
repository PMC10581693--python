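"""Ancestral state reconstruction for traitgrams and composition bars.

Two reconstructions are provided.  Discrete nucleotide-composition
states (fractions of A/C/G/T on a 0.05 grid) are reconstructed by
Sankoff parsimony with an L1 transition cost.  Continuous traits (the +4
A:U log2 ratio) are reconstructed by maximum likelihood under Brownian
motion; jointly maximising over the internal states reduces to a sparse
weighted-least-squares problem on the tree, and the root estimate
coincides with the GLS phylogenetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .phylo import PhyloNode, PhyloTree, node_times, tree_covariance

__all__ = [
    "CompositionState",
    "composition_states",
    "round_to_grid",
    "sankoff_fractions",
    "bm_ancestral",
    "traitgram_table",
]

_MIN_BRANCH = 1e-12  # zero-length branches clamp here in the BM solver


@dataclass(frozen=True)
class CompositionState:
    """A/C/G/T fractions on a grid of multiples of ``step``, summing to 1."""

    fractions: tuple[float, float, float, float]
    step: float = 0.05

    def __post_init__(self):
        k = round(1 / self.step)
        units = [round(f * k) for f in self.fractions]
        off_grid = any(abs(f * k - u) > 1e-6 for f, u in zip(self.fractions, units))
        if off_grid or any(u < 0 for u in units) or sum(units) != k:
            raise ValueError(
                f"fractions must be non-negative multiples of {self.step} summing to 1"
            )


def _state_units(step: float) -> np.ndarray:
    """All grid states in units of ``step``, lexicographically sorted."""
    k = round(1 / step)
    if abs(k * step - 1) > 1e-9:
        raise ValueError("step must divide 1 exactly")
    states = []
    for cuts in combinations_with_replacement(range(k + 1), 3):
        a = cuts[0]
        c = cuts[1] - cuts[0]
        g = cuts[2] - cuts[1]
        t = k - cuts[2]
        states.append((a, c, g, t))
    states.sort()
    return np.array(states, dtype=np.int64)


def composition_states(step: float = 0.05) -> np.ndarray:
    """Grid of composition states as fractions, lexicographically sorted."""
    units = _state_units(step)
    return units / round(1 / step)


def round_to_grid(fractions, step: float = 0.05) -> CompositionState:
    """Round raw fractions to the grid by the largest-remainder method.

    Plain per-entry rounding can break the sum-to-one constraint; largest
    remainder allocates the residual units to the entries that lose most
    by truncation (ties broken by nucleotide order, so deterministic).
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (4,) or np.any(f < 0):
        raise ValueError("need 4 non-negative fractions")
    total = f.sum()
    if total <= 0:
        raise ValueError("fractions sum to zero")
    f = f / total
    k = round(1 / step)
    scaled = f * k
    units = np.floor(scaled).astype(int)
    remainder = scaled - units
    for idx in np.argsort(-remainder, kind="stable")[: k - units.sum()]:
        units[idx] += 1
    return CompositionState(tuple(units / k), step)


def _cost_matrix(units: np.ndarray, cost: str):
    """Pairwise transition costs between grid states.

    L1 costs are returned as exact integers in grid units so that
    parsimony ties are resolved without floating-point noise.
    """
    if cost == "L1":
        return np.abs(units[:, None, :] - units[None, :, :]).sum(axis=2)
    if cost == "L2":
        k = units.sum(axis=1).max()  # grid resolution: fractions = units / k
        diff = (units[:, None, :] - units[None, :, :]) / k
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError("cost must be 'L1' or 'L2'")


def sankoff_fractions(
    tree: PhyloTree,
    leaf_states: dict[str, "CompositionState | tuple | np.ndarray"],
    step: float = 0.05,
    cost: str = "L1",
) -> tuple[dict[PhyloNode, CompositionState], float]:
    """Minimum-cost ancestral composition states by Sankoff parsimony.

    Bottom-up dynamic programming over the full grid of composition
    states, followed by a top-down traceback.  Ties are broken towards
    the lexicographically smallest state tuple.  Leaf fractions not on
    the grid are first rounded by the largest-remainder method.  Returns
    the node-to-state assignment (leaves included) and the total cost in
    fraction units.
    """
    missing = set(tree.leaf_labels) - set(leaf_states)
    if missing:
        raise KeyError(f"no state for leaves: {', '.join(sorted(missing))}")
    units = _state_units(step)
    k = round(1 / step)
    S = len(units)
    C = _cost_matrix(units, cost)
    index_of = {tuple(u): i for i, u in enumerate(units)}

    def leaf_index(label: str) -> int:
        st = leaf_states[label]
        fr = st.fractions if isinstance(st, CompositionState) else st
        st = round_to_grid(np.asarray(fr, dtype=float), step)
        return index_of[tuple(round(f * k) for f in st.fractions)]

    big = np.iinfo(np.int64).max // 4 if cost == "L1" else np.inf
    node_cost: dict[PhyloNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(S, big, dtype=C.dtype)
            vec[leaf_index(node.label)] = 0
        else:
            vec = np.zeros(S, dtype=C.dtype)
            for child in node.children:
                # min over child states of (transition cost + child cost)
                vec = vec + (C + node_cost[child][None, :]).min(axis=1)
        node_cost[node] = vec
    assignment: dict[PhyloNode, CompositionState] = {}
    root_idx = int(np.argmin(node_cost[tree.root]))
    total = float(node_cost[tree.root][root_idx]) / (k if cost == "L1" else 1.0)
    choice: dict[PhyloNode, int] = {tree.root: root_idx}
    for node in tree.preorder():
        idx = choice[node]
        assignment[node] = CompositionState(tuple(units[idx] / k), step)
        for child in node.children:
            choice[child] = int(np.argmin(C[idx] + node_cost[child]))
    return assignment, total


def bm_ancestral(
    tree: PhyloTree, tip_values: dict[str, float]
) -> dict[PhyloNode, tuple[float, float]]:
    """ML ancestral estimates of a continuous trait under Brownian motion.

    The joint likelihood over internal states factorises over branches as
    independent Gaussian increments, so for any rate the ML internal
    states minimise sum((x_parent - x_child)^2 / branch_length) with tips
    fixed -- a sparse linear system.  Variances are the conditional
    variances of internal states given the tips, scaled by the ML rate
    estimate from the tips.  Tips return their observed value with
    variance 0.
    """
    labels = tree.leaf_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 tips")
    missing = set(labels) - set(tip_values)
    if missing:
        raise KeyError(f"no value for tips: {', '.join(sorted(missing))}")
    internals = [n for n in tree.preorder() if not n.is_leaf]
    pos = {n: i for i, n in enumerate(internals)}
    m = len(internals)
    P = np.zeros((m, m))
    b = np.zeros(m)
    for node in tree.preorder():
        if node is tree.root:
            continue
        w = 1.0 / max(node.branch_length, _MIN_BRANCH)
        pi = pos[node.parent]
        if node.is_leaf:
            P[pi, pi] += w
            b[pi] += w * tip_values[node.label]
        else:
            ci = pos[node]
            P[pi, pi] += w
            P[ci, ci] += w
            P[pi, ci] -= w
            P[ci, pi] -= w
    P_inv = np.linalg.inv(P)
    est = P_inv @ b
    # ML Brownian rate from the tips alone
    y = np.array([tip_values[l] for l in labels])
    V = tree_covariance(tree, labels).values
    V = V + _MIN_BRANCH * np.eye(len(y))
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones_like(y))
    mu = float(np.sum(Vinv_y) / np.sum(Vinv_1))
    r = y - mu
    sigma2 = float(r @ np.linalg.solve(V, r)) / len(y)
    out: dict[PhyloNode, tuple[float, float]] = {}
    for node in tree.preorder():
        if node.is_leaf:
            out[node] = (float(tip_values[node.label]), 0.0)
        else:
            i = pos[node]
            out[node] = (float(est[i]), float(sigma2 * P_inv[i, i]))
    return out


def node_ids(tree: PhyloTree) -> dict[PhyloNode, str]:
    """Stable node identifiers: leaf labels, or N<i> in preorder."""
    ids = {}
    counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            ids[node] = node.label
        else:
            ids[node] = node.label or f"N{counter}"
        if not node.is_leaf:
            counter += 1
    return ids


def traitgram_table(tree: PhyloTree, tip_values: dict[str, float]) -> pd.DataFrame:
    """Node coordinates for a traitgram: time on x, trait on y.

    Tips carry their observed values; internal nodes carry Brownian ML
    estimates.  Drawing a segment from each node to its parent renders
    the traitgram (node count - 1 segments).
    """
    anc = bm_ancestral(tree, tip_values)
    times = node_times(tree)
    ids = node_ids(tree)
    rows = []
    for node in tree.preorder():
        est, var = anc[node]
        rows.append(
            {
                "node": ids[node],
                "time": times[node],
                "estimate": est,
                "variance": var,
                "parent": ids[node.parent] if node.parent else "",
                "is_leaf": node.is_leaf,
            }
        )
    return pd.DataFrame(rows)
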