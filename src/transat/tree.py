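"""Rooted binary phylogenies with branch lengths.

Trees are stored as flat arrays (children per node, branch length of the
edge above each node) so that the pruning likelihood can run as plain numpy
loops.  Parsing is delegated to dendropy; an unrooted Newick tree whose root
trifurcates is resolved into a binary root by inserting a zero-length edge,
which leaves likelihoods of reversible models unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError


@dataclass
class PhyloTree:
    """A rooted binary tree with non-negative branch lengths.

    ``children[k]`` is a ``(left, right)`` tuple for internal nodes and
    ``None`` for leaves; ``branch_lengths[k]`` is the length of the edge
    above node ``k`` (0 for the root); ``labels[k]`` is the taxon name for
    leaves and ``None`` otherwise.  ``root`` is the root node index.
    """

    children: list[tuple[int, int] | None]
    branch_lengths: np.ndarray
    labels: list[str | None]
    root: int
    _postorder: list[int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.children)
        if not (len(self.labels) == n == len(self.branch_lengths)):
            raise TreeError("inconsistent tree arrays")
        if np.any(self.branch_lengths < 0):
            raise TreeError("negative branch length")
        leaves = [self.labels[k] for k in range(n) if self.children[k] is None]
        if any(lab is None for lab in leaves):
            raise TreeError("unlabeled leaf")
        if len(set(leaves)) != len(leaves):
            raise TreeError("duplicate leaf labels")

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_leaves(self) -> int:
        return sum(1 for c in self.children if c is None)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[k] for k in self.leaf_indices()]

    def leaf_indices(self) -> list[int]:
        return [k for k in range(self.n_nodes) if self.children[k] is None]

    def postorder(self) -> list[int]:
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, expanded = stack.pop()
                kids = self.children[node]
                if kids is None or expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    stack.extend((k, False) for k in reversed(kids))
            self._postorder = order
        return self._postorder

    def total_length(self) -> float:
        """Sum of all branch lengths (the root carries no edge)."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.branch_lengths[mask].sum())

    def to_newick(self) -> str:
        def render(node: int) -> str:
            kids = self.children[node]
            if kids is None:
                body = self.labels[node]
            else:
                body = "(" + ",".join(render(k) for k in kids) + ")"
            if node == self.root:
                return f"{body};"
            return f"{body}:{self.branch_lengths[node]:.10g}"

        return render(self.root)


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    seed = dtree.seed_node
    for node in dtree.preorder_node_iter():
        n_kids = len(node.child_nodes())
        if node is seed:
            if n_kids not in (0, 2, 3):
                raise TreeError(
                    f"root has {n_kids} children; only a trifurcating root "
                    "can be resolved"
                )
        elif n_kids not in (0, 2):
            raise TreeError(f"polytomy ({n_kids} children) below the root")

    children: list[tuple[int, int] | None] = []
    lengths: list[float] = []
    labels: list[str | None] = []

    def add(node: dendropy.Node, at_root: bool) -> int:
        kids = node.child_nodes()
        length = 0.0 if at_root else node.edge.length
        if length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeError(f"missing branch length above node {name}")
        if kids:
            kid_ids = [add(k, False) for k in kids]
            if len(kid_ids) == 3:
                # Unrooted convention: keep the first child, gather the other
                # two under a new zero-length internal edge.
                children.append((kid_ids[1], kid_ids[2]))
                lengths.append(0.0)
                labels.append(None)
                kid_ids = [kid_ids[0], len(children) - 1]
            children.append(tuple(kid_ids))  # type: ignore[arg-type]
            lengths.append(float(length))
            labels.append(None)
        else:
            if node.taxon is None:
                raise TreeError("leaf without a taxon label")
            children.append(None)
            lengths.append(float(length))
            labels.append(node.taxon.label)
        return len(children) - 1

    root = add(seed, at_root=True)
    tree = PhyloTree(children, np.asarray(lengths, dtype=float), labels, root)
    if tree.n_leaves < 2:
        raise TreeError("a tree needs at least 2 leaves")
    return tree


def read_tree(path: str) -> PhyloTree:
    """Read a rooted binary tree (Newick) with branch lengths."""
    try:
        dtree = dendropy.Tree.get(
            path=path,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, FileNotFoundError) as exc:
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return _from_dendropy(dtree)


def tree_from_newick_string(newick: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise TreeError(f"cannot parse Newick string: {exc}") from exc
    return _from_dendropy(dtree)


def total_tree_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths; the evolutionary-diversity proxy."""
    return tree.total_length()
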