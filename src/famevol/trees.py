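"""Dated species trees.

A thin wrapper over :class:`dendropy.Tree` that fixes the conventions the
rest of the package relies on: a rooted tree, branch lengths in million
years, unique tip names (species codes), and stable node labels so that
branches can be referred to by the label of their child node.
"""

from __future__ import annotations

import io
from typing import Iterator, List, Optional

import dendropy


class SpeciesTree:
    """Rooted dated species tree with labelled nodes.

    Internal nodes are labelled ``N0``, ``N1``, ... in preorder (``N0`` is
    the root); tips keep their taxon names.  A branch is identified by the
    label of the node at its child end.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        require_binary: bool = True,
        require_lengths: bool = True,
    ):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self._tree = tree
        self._label_nodes()
        self._validate(require_binary, require_lengths)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str,
        require_binary: bool = True,
        require_lengths: bool = True,
    ) -> "SpeciesTree":
        """Parse a Newick string or file path."""
        text = source
        if "(" not in source:  # looks like a path, not a tree
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls(tree, require_binary=require_binary, require_lengths=require_lengths)

    def _label_nodes(self) -> None:
        i = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("tip without a name")
                node.label = node.taxon.label
            else:
                node.label = f"N{i}"
                i += 1

    def _validate(self, require_binary: bool, require_lengths: bool) -> None:
        tips = self.tip_names
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip names")
        for node in self._tree.preorder_node_iter():
            nch = len(node.child_nodes())
            if node is self.root:
                if require_binary and nch not in (0, 2):
                    raise ValueError(f"root has {nch} children; expected a binary tree")
            else:
                if require_binary and nch not in (0, 2):
                    raise ValueError(
                        f"polytomy or unifurcation at node {node.label!r}; "
                        "the reconciliation model assumes a binary tree"
                    )
                length = node.edge.length
                if require_lengths:
                    if length is None:
                        raise ValueError(f"missing branch length above {node.label!r}")
                    if not (length >= 0):
                        raise ValueError(f"negative branch length above {node.label!r}")

    # -- accessors ------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_names(self) -> List[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        for n in self._tree.preorder_node_iter():
            if n.label == label:
                return n
        raise KeyError(label)

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def branches(self) -> List[dendropy.Node]:
        """Non-root nodes; each stands for the branch above it."""
        return [n for n in self._tree.preorder_node_iter() if n is not self.root]

    def branch_length(self, label: str) -> float:
        node = self.node(label)
        if node is self.root:
            raise ValueError("the root has no branch above it")
        return float(node.edge.length if node.edge.length is not None else 0.0)

    @property
    def n_branches(self) -> int:
        return len(self.branches())

    def total_time(self) -> float:
        """Sum of all branch lengths (My)."""
        return sum(
            float(n.edge.length or 0.0) for n in self.branches()
        )

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __len__(self) -> int:
        return len(self.tip_names)

    def __repr__(self) -> str:
        return f"SpeciesTree({len(self)} tips, {self.n_branches} branches)"
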