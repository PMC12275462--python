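"""Rooted phylogenetic trees with branch lengths.

The tree is stored as flat arrays indexed by node id, with nodes numbered
in postorder (children before parents, root last).  A *branch* is
identified by the id of the node at its child end, so every non-root node
carries exactly one branch and its length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "NewickError", "read_newick", "write_newick"]


class NewickError(ValueError):
    """Raised for malformed or unsupported newick input."""


@dataclass
class PhyloTree:
    """A rooted tree in postorder array form.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[root] == -1``.
    lengths : (n_nodes,) float array; branch length above each node in
        expected substitutions per site.  ``lengths[root] == 0``.
    names : tip name for each node, ``None`` for internal nodes.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str | None]
    children: list[list[int]] = field(init=False, repr=False)
    tip_ids: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.names)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if self.parent.shape != (n,) or self.lengths.shape != (n,):
            raise ValueError("parent, lengths and names must have equal length")
        if int((self.parent == -1).sum()) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        self.children = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                if p <= i:
                    raise ValueError("nodes must be numbered in postorder")
                self.children[p].append(i)
        self.tip_ids = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        tips = [self.names[i] for i in self.tip_ids]
        if any(t is None for t in tips):
            raise ValueError("every tip must be named")
        if len(set(tips)) != len(tips):
            raise ValueError("tip names must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_names(self) -> list[str]:
        return [self.names[i] for i in self.tip_ids]  # type: ignore[misc]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tip_index(self) -> dict[str, int]:
        """Map tip name -> node id."""
        return {self.names[i]: int(i) for i in self.tip_ids}  # type: ignore[misc]

    def clade_tips(self, node: int) -> frozenset[str]:
        """Names of all tips descending from (and including) ``node``."""
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(self.names[v])  # type: ignore[arg-type]
            else:
                stack.extend(self.children[v])
        return frozenset(out)

    def rescale(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths * factor, list(self.names))


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n, dtype=np.float64)
    names: list[str | None] = [None] * n
    for i, nd in enumerate(order):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickError("missing branch length on a non-root branch")
            if nd.edge.length < 0:
                raise NewickError("negative branch length")
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("unnamed tip")
            names[i] = nd.taxon.label
    return PhyloTree(parent, lengths, names)


def read_newick(text: str) -> PhyloTree:
    """Parse a single rooted newick statement into a :class:`PhyloTree`.

    Every non-root branch must carry a length; tip names must be unique.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"could not parse newick: {exc}") from exc
    try:
        return _from_dendropy(dtree)
    except ValueError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree back to newick (branch lengths in full precision)."""

    def fmt(node: int) -> str:
        if tree.is_tip(node):
            label = tree.names[node]
        else:
            label = "(" + ",".join(fmt(c) for c in tree.children[node]) + ")"
        if tree.parent[node] == -1:
            return label
        return f"{label}:{tree.lengths[node]:.10g}"

    return fmt(tree.root) + ";"
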