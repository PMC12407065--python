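"""Time-calibrated phylogenies and Brownian-motion covariance structure.

Under Brownian motion on a rooted tree with branch lengths in time
units, trait values at any set of nodes are jointly multivariate normal;
the covariance of two nodes is proportional to the depth (root-to-node
path length) of their most recent common ancestor.  This module wraps a
dendropy tree and precomputes those shared path lengths, which drive
PGLS regression, ancestral-state reconstruction, and trait simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees (negative branch lengths, label clashes)."""


@dataclass
class _Node:
    index: int
    parent: int | None
    edge_length: float
    depth: float
    label: str
    tip_index: int | None  # None for internal nodes
    children: list[int]


class PhyloTree:
    """Rooted, time-calibrated tree with Brownian covariance helpers.

    Parameters
    ----------
    tree
        A rooted :class:`dendropy.Tree` with non-negative branch lengths.
        Missing root edge lengths are treated as zero.

    Attributes
    ----------
    taxa
        Tip labels, in a fixed (leaf-iteration) order; all covariance
        matrices and simulated trait vectors follow this order.
    """

    def __init__(self, tree: dendropy.Tree):
        self._dendropy = tree
        self._build(tree)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Parse a Newick tree from a file path or a literal string."""
        src = str(source)
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
        return cls(tree)

    def _build(self, tree: dendropy.Tree) -> None:
        nodes: list[_Node] = []
        taxa: list[str] = []
        index_of: dict[int, int] = {}
        n_unnamed = 0
        for nd in tree.preorder_node_iter():
            el = nd.edge.length
            el = 0.0 if el is None else float(el)
            if el < 0:
                raise TreeError("negative branch length")
            parent = index_of[id(nd.parent_node)] if nd.parent_node is not None else None
            depth = el + (nodes[parent].depth if parent is not None else 0.0)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeError("unlabelled tip")
                label = nd.taxon.label
                tip_index = len(taxa)
                taxa.append(label)
            else:
                label = nd.label or f"node{len(nodes)}"
                tip_index = None
            idx = len(nodes)
            index_of[id(nd)] = idx
            nodes.append(_Node(idx, parent, el, depth, label, tip_index, []))
            if parent is not None:
                nodes[parent].children.append(idx)
        if len(set(taxa)) != len(taxa):
            raise TreeError("duplicate tip labels")
        self._nodes = nodes
        self.taxa = taxa
        self.n_tips = len(taxa)
        # descendant tip sets, bottom-up
        tip_sets: list[set[int]] = [set() for _ in nodes]
        for node in reversed(nodes):
            if node.tip_index is not None:
                tip_sets[node.index].add(node.tip_index)
            if node.parent is not None:
                tip_sets[node.parent] |= tip_sets[node.index]
        self._tip_sets = tip_sets
        self._tip_cov: np.ndarray | None = None

    # -- structure accessors ----------------------------------------------

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self._nodes if n.tip_index is None]

    @property
    def node_labels(self) -> list[str]:
        return [n.label for n in self._nodes]

    def edges(self) -> list[tuple[str, str]]:
        """(parent label, child label) pairs over the whole tree."""
        return [
            (self._nodes[n.parent].label, n.label)
            for n in self._nodes
            if n.parent is not None
        ]

    def tip_depths(self) -> np.ndarray:
        out = np.empty(self.n_tips)
        for n in self._nodes:
            if n.tip_index is not None:
                out[n.tip_index] = n.depth
        return out

    def terminal_branch_lengths(self) -> np.ndarray:
        out = np.empty(self.n_tips)
        for n in self._nodes:
            if n.tip_index is not None:
                out[n.tip_index] = n.edge_length
        return out

    # -- Brownian covariance ----------------------------------------------

    def tip_covariance(self) -> np.ndarray:
        """Brownian covariance C of tips: C[i, j] = depth of MRCA(i, j).

        Symmetric positive semi-definite; the diagonal holds root-to-tip
        distances.
        """
        if self._tip_cov is not None:
            return self._tip_cov
        n = self.n_tips
        C = np.zeros((n, n))
        for node in self._nodes:
            if node.tip_index is not None:
                C[node.tip_index, node.tip_index] = node.depth
                continue
            kids = node.children
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    a = sorted(self._tip_sets[kids[i]])
                    b = sorted(self._tip_sets[kids[j]])
                    C[np.ix_(a, b)] = node.depth
                    C[np.ix_(b, a)] = node.depth
        self._tip_cov = C
        return C

    def internal_tip_covariance(self) -> np.ndarray:
        """Covariance between internal nodes (rows) and tips (columns).

        Entry (j, i) is the depth of the MRCA of internal node j and tip
        i: node j's own depth when the tip descends from it, otherwise
        the depth of their deepest common ancestor.
        """
        internals = [n for n in self._nodes if n.tip_index is None]
        out = np.zeros((len(internals), self.n_tips))
        for row, node in enumerate(internals):
            # walk rootward from the node, assigning ancestor depths to
            # tips first covered at each step
            covered = set(self._tip_sets[node.index])
            for t in covered:
                out[row, t] = node.depth
            cur = node
            while cur.parent is not None:
                parent = self._nodes[cur.parent]
                newly = self._tip_sets[parent.index] - covered
                for t in newly:
                    out[row, t] = parent.depth
                covered |= newly
                cur = parent
        return out

    def reorder(self, taxa: list[str]) -> np.ndarray:
        """Index array mapping this tree's tip order onto ``taxa``."""
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise TreeError(f"taxa absent from tree: {missing}")
        return np.array([pos[t] for t in taxa], dtype=int)

    def as_dendropy(self) -> dendropy.Tree:
        return self._dendropy

    def write_newick(self, path: str | Path) -> None:
        self._dendropy.write(path=str(path), schema="newick")
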