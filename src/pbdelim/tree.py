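"""Rooted lineage trees.

A :class:`LineageTree` wraps a validated :class:`dendropy.Tree`.  Tips are
population lineages (typically from a prior multispecies-coalescent analysis),
and every branch carries a strictly positive duration in the same time units
as the reciprocal of the speciation-completion rate.  The root has no branch
above it, so a binary tree with ``n`` leaves has exactly ``2n - 2`` branches;
polytomies are permitted (and then the branch count is smaller).

Branches are identified by their child node and are exposed in a fixed
postorder, so downstream code (event configurations, the likelihood dynamic
program, the simulator) can address branches by integer index.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .exceptions import InputError, TreeStructureError

logger = logging.getLogger(__name__)

__all__ = ["LineageTree", "extract_induced_tree"]


class LineageTree:
    """A rooted tree of population lineages with branch durations.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree.  Every non-root node must have a positive edge length;
        leaf labels must be unique, non-empty strings.  Any edge length on the
        root itself is discarded (there is no branch above the root).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        """Parse a single Newick string (quoted labels and bracketed comments
        follow the standard dialect)."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise InputError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        tree = self._tree
        seed = tree.seed_node
        if seed.edge.length is not None:
            logger.warning(
                "discarding branch length %s above the root (a lineage tree "
                "has no stem branch)",
                seed.edge.length,
            )
            seed.edge.length = None
        leaves = tree.leaf_nodes()
        if len(leaves) < 2:
            raise TreeStructureError("a lineage tree needs at least 2 leaves")
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeStructureError("every leaf needs a non-empty label")
            labels.append(label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeStructureError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node is seed:
                if len(node.child_nodes()) > 2:
                    logger.warning(
                        "root has %d children; treating as a rooted polytomy",
                        len(node.child_nodes()),
                    )
                continue
            length = node.edge.length
            if length is None:
                raise TreeStructureError(
                    f"branch above {_describe(node)} has no duration; the "
                    "partition likelihood is undefined without durations"
                )
            if not length > 0:
                raise TreeStructureError(
                    f"branch above {_describe(node)} has non-positive "
                    f"duration {length}"
                )

    def _index(self) -> None:
        self._postorder = tuple(self._tree.postorder_node_iter())
        self._branches = tuple(
            node for node in self._postorder if node is not self._tree.seed_node
        )
        self._branch_index = {node: i for i, node in enumerate(self._branches)}
        self._branch_lengths = np.array(
            [node.edge.length for node in self._branches], dtype=float
        )
        self._leaves = tuple(
            node for node in self._postorder if node.is_leaf()
        )
        self._leaf_labels = tuple(node.taxon.label for node in self._leaves)

    # -- basic structure ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def leaf_labels(self) -> tuple:
        """Leaf labels in postorder."""
        return self._leaf_labels

    @property
    def leaf_label_set(self) -> frozenset:
        return frozenset(self._leaf_labels)

    @property
    def branches(self) -> tuple:
        """Non-root nodes in postorder; branch *i* is the edge above
        ``branches[i]``."""
        return self._branches

    @property
    def n_branches(self) -> int:
        return len(self._branches)

    @property
    def branch_lengths(self) -> np.ndarray:
        """Durations aligned with :attr:`branches` (copy-safe view)."""
        return self._branch_lengths

    @property
    def total_length(self) -> float:
        return float(self._branch_lengths.sum())

    def branch_index(self, node: dendropy.Node) -> int:
        return self._branch_index[node]

    def postorder_nodes(self) -> tuple:
        return self._postorder

    def leaf_depths(self) -> dict:
        """Root-to-tip path length per leaf label."""
        depth = {self.root: 0.0}
        out = {}
        for node in self._tree.preorder_node_iter():
            if node is self.root:
                continue
            depth[node] = depth[node.parent_node] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label] = depth[node]
        return out

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def __repr__(self) -> str:
        return f"<LineageTree with {self.n_leaves} leaves>"

    # -- induced trees -----------------------------------------------------

    def extract_induced_tree(self, leaf_subset) -> "LineageTree":
        """Tree connecting ``leaf_subset``, rooted at their MRCA.

        Degree-2 nodes are suppressed with their branch durations summed, so
        every pairwise path length among retained leaves is preserved.
        """
        subset = set(leaf_subset)
        unknown = subset - self.leaf_label_set
        if unknown:
            raise InputError(f"labels not in tree: {sorted(unknown)}")
        if len(subset) < 2:
            raise InputError("an induced tree needs at least 2 leaves")
        sub = self._tree.extract_tree_with_taxa_labels(labels=subset)
        # extract_tree_with_taxa_labels reroots at the MRCA but may keep the
        # original stem path as an edge length on the new root; drop it.
        sub.seed_node.edge.length = None
        return LineageTree(sub)


def extract_induced_tree(tree: LineageTree, leaf_subset) -> LineageTree:
    """Functional form of :meth:`LineageTree.extract_induced_tree`."""
    return tree.extract_induced_tree(leaf_subset)


def _describe(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"leaf {node.taxon.label!r}"
    tips = [l.taxon.label for l in node.leaf_iter()][:3]
    return f"internal node above {tips}..."
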