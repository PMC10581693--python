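"""Rooted phylogenies: Newick I/O, trait covariance, Dollo loss counting.

The tree is the backbone of every downstream analysis: it supplies the
phylogenetic variance-covariance matrix used by the GLS association tests,
the single-gain / irreversible-loss (Dollo) parsimony used to count
independent gene-loss events, and the node-time coordinates used for
traitgrams and ancestral reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "CovarianceMatrix",
    "NewickError",
    "parse_newick",
    "tree_covariance",
    "dollo_losses",
    "node_times",
]


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


@dataclass(eq=False)
class PhyloNode:
    """A node of a rooted tree.

    ``branch_length`` is the length of the edge to the parent and is
    ``0.0`` for the root.  Internal nodes may carry empty labels; leaf
    labels are unique and non-empty.
    """

    label: str = ""
    branch_length: float = 0.0
    parent: "PhyloNode | None" = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<PhyloNode {self.label or '?'} {kind} bl={self.branch_length:g}>"


class PhyloTree:
    """Rooted tree with branch lengths and uniquely labelled leaves."""

    def __init__(self, root: PhyloNode):
        self.root = root
        self._index_leaves()

    def _index_leaves(self) -> None:
        self.leaves: list[PhyloNode] = [n for n in self.postorder() if n.is_leaf]
        labels = [leaf.label for leaf in self.leaves]
        if any(not lab for lab in labels):
            raise NewickError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {', '.join(dupes)}")
        self.leaf_map: dict[str, PhyloNode] = dict(zip(labels, self.leaves))
        for node in self.postorder():
            if node is not self.root and node.branch_length < 0:
                raise NewickError("negative branch length")

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves]

    def postorder(self):
        """Yield nodes children-before-parents."""
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self):
        """Yield nodes parents-before-children."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def mrca(self, labels) -> PhyloNode:
        """Most recent common ancestor of a set of leaf labels."""
        target = set(labels)
        unknown = target - set(self.leaf_map)
        if unknown:
            raise KeyError(f"unknown taxa: {', '.join(sorted(unknown))}")
        below: dict[PhyloNode, int] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = 1 if node.label in target else 0
            else:
                below[node] = sum(below[c] for c in node.children)
        node = self.root
        n = len(target)
        while True:
            nxt = [c for c in node.children if below[c] == n]
            if not nxt:
                return node
            node = nxt[0]

    def leaves_under(self, node: PhyloNode) -> list[PhyloNode]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(reversed(n.children))
        return out

    def to_newick(self) -> str:
        def render(node: PhyloNode) -> str:
            if node.is_leaf:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.label:
                    core += _quote_label(node.label)
            if node is self.root:
                return core
            return f"{core}:{node.branch_length:g}"

        return render(self.root) + ";"

    def __len__(self) -> int:
        return len(self.leaves)


def _quote_label(label: str) -> str:
    if any(c in label for c in "():;, '\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str, missing_lengths: str = "error") -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Parameters
    ----------
    text:
        Newick string with branch lengths.
    missing_lengths:
        ``"error"`` rejects edges without a length; ``"unit"`` assigns
        length 1.0 to them.

    Raises
    ------
    NewickError
        On malformed input, duplicate leaf labels, explicit unrooted
        (``[&U]``) annotation, or missing lengths under the default policy.
    """
    if missing_lengths not in ("error", "unit"):
        raise ValueError("missing_lengths must be 'error' or 'unit'")
    if "[&u]" in text.lower():
        raise NewickError("unrooted trees are not supported; root via outgroup first")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode, parent):
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        bl = dnode.edge.length
        if parent is None:
            bl = 0.0
        elif bl is None:
            if missing_lengths == "error":
                raise NewickError(
                    f"missing branch length above {label or 'an internal node'}"
                )
            bl = 1.0
        node = PhyloNode(label=label, branch_length=float(bl), parent=parent)
        if parent is not None:
            parent.children.append(node)
        for dchild in dnode.child_nodes():
            convert(dchild, node)
        return node

    root = convert(dtree.seed_node, None)
    # A bare "(A:1);" parses to a root with one child; keep that shape.
    return PhyloTree(root)


def node_times(tree: PhyloTree) -> dict[PhyloNode, float]:
    """Root-to-node path length for every node (root maps to 0)."""
    times: dict[PhyloNode, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            times[node] = 0.0
        else:
            times[node] = times[node.parent] + node.branch_length
    return times


@dataclass
class CovarianceMatrix:
    """Phylogenetic variance-covariance matrix over an ordered taxon set.

    Diagonal entries are root-to-leaf distances; off-diagonal entries are
    root-to-MRCA distances (the shared path length under Brownian motion).
    """

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")

    def subset(self, taxa) -> "CovarianceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CovarianceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="taxon")


def tree_covariance(tree: PhyloTree, taxa=None) -> CovarianceMatrix:
    """Brownian-motion covariance matrix implied by a rooted tree.

    ``var(i)`` is the root-to-leaf distance of taxon *i*; ``cov(i, j)`` is
    the root-to-MRCA distance of the pair.  Rows and columns follow the
    requested ``taxa`` order (default: the tree's leaf order).
    """
    if taxa is None:
        taxa = tree.leaf_labels
    taxa = list(taxa)
    unknown = set(taxa) - set(tree.leaf_map)
    if unknown:
        raise KeyError(f"unknown taxa: {', '.join(sorted(unknown))}")
    times = node_times(tree)
    pos = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    cov = np.zeros((n, n))
    for label in taxa:
        cov[pos[label], pos[label]] = times[tree.leaf_map[label]]
    # cov(i, j) = time of MRCA(i, j): walk nodes top-down; pairs of leaves
    # split across different children of a node have that node as MRCA.
    for node in tree.preorder():
        if node.is_leaf:
            continue
        groups = []
        for child in node.children:
            idx = [pos[l.label] for l in tree.leaves_under(child) if l.label in pos]
            if idx:
                groups.append(np.array(idx))
        t = times[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                cov[np.ix_(groups[a], groups[b])] = t
                cov[np.ix_(groups[b], groups[a])] = t
    if n > 1:
        d = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 0.0)
        if np.any(np.nan_to_num(corr) >= 1.0 - 1e-12):
            warnings.warn(
                "zero-length branches give perfectly correlated taxa; "
                "the covariance matrix is singular",
                stacklevel=2,
            )
    return CovarianceMatrix(taxa, cov)


def dollo_losses(tree: PhyloTree, presence: dict[str, int]) -> tuple[int, PhyloNode]:
    """Minimum loss count under single-gain, irreversible-loss evolution.

    The gene is gained once, on the branch above the MRCA of all present
    leaves, and each maximal all-absent subtree below that MRCA requires
    one independent loss.  Returns ``(loss_count, gain_node)``.

    Leaves missing from ``presence`` are treated as absent.
    """
    present = [lab for lab in tree.leaf_labels if presence.get(lab, 0)]
    if not present:
        raise ValueError("all-absent genotype: no presence to explain")
    gain = tree.mrca(present)
    present_set = set(present)
    absent_all: dict[PhyloNode, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            absent_all[node] = node.label not in present_set
        else:
            absent_all[node] = all(absent_all[c] for c in node.children)
    losses = 0
    stack = [gain]
    while stack:
        node = stack.pop()
        for child in node.children:
            if absent_all[child]:
                losses += 1  # maximal absent subtree: one loss event
            else:
                stack.append(child)
    return losses, gain


def dollo_loss_branches(tree: PhyloTree, presence: dict[str, int]) -> list[PhyloNode]:
    """Roots of the maximal all-absent subtrees under the Dollo gain node.

    Each returned node heads one inferred loss event; used to annotate
    loss branches on traitgrams.
    """
    _, gain = dollo_losses(tree, presence)
    present_set = {lab for lab in tree.leaf_labels if presence.get(lab, 0)}
    absent_all: dict[PhyloNode, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            absent_all[node] = node.label not in present_set
        else:
            absent_all[node] = all(absent_all[c] for c in node.children)
    out: list[PhyloNode] = []
    stack = [gain]
    while stack:
        node = stack.pop()
        for child in node.children:
            if absent_all[child]:
                out.append(child)
            else:
                stack.append(child)
    return out
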