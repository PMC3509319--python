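"""Rooted trees: a light node structure plus Newick I/O and tree comparison.

Newick parsing is delegated to dendropy; the parsed tree is converted to a
small mutable node structure that the UPGMA builder and the reconciliation
engine manipulate directly. Canonical Newick output orders children by their
smallest descendant leaf label, so round trips are string-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


@dataclass(eq=False)  # identity semantics: nodes are places in a tree
class Node:
    label: str | None = None
    length: float | None = None  # branch length to parent
    height: float | None = None  # ultrametric node height (UPGMA output)
    support: float | None = None  # bipartition support in [0, 1]
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RootedTree:
    root: Node

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        labels = [n.label for n in self.leaves()]
        if any(l is None for l in labels):
            raise TreeError("tree contains unlabelled leaves")
        return labels  # type: ignore[return-value]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(label)

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def clades(self) -> dict[int, frozenset[str]]:
        """Leaf-label set below each node, keyed by ``id(node)``."""
        out: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                out[id(n)] = frozenset([n.label])  # type: ignore[list-item]
            else:
                s: frozenset[str] = frozenset()
                for c in n.children:
                    s |= out[id(c)]
                out[id(n)] = s
        return out

    def copy(self) -> "RootedTree":
        def _copy(node: Node) -> Node:
            new = Node(label=node.label, length=node.length,
                       height=node.height, support=node.support)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return RootedTree(root=_copy(self.root))

    def depths(self) -> dict[int, int]:
        """Topological depth per node id; root depth 0, increasing toward leaves."""
        out = {id(self.root): 0}
        for n in self.preorder():
            for c in n.children:
                out[id(c)] = out[id(n)] + 1
        return out


# ---------------------------------------------------------------------------
# Newick I/O

def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label is not None:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    if not dnode.is_leaf() and dnode.label is not None:
        # internal labels may carry bootstrap support
        try:
            node.support = float(dnode.label)
            node.label = None
        except ValueError:
            pass
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Internal node labels that parse as numbers are interpreted as support
    values. Malformed input raises :class:`TreeError`.
    """
    if not text.strip():
        raise TreeError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    tree = RootedTree(root=_from_dendropy(dtree.seed_node))
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    return tree


def _min_leaf(node: Node, cache: dict[int, str]) -> str:
    if id(node) in cache:
        return cache[id(node)]
    if node.is_leaf:
        val = node.label or ""
    else:
        val = min(_min_leaf(c, cache) for c in node.children)
    cache[id(node)] = val
    return val


def write_newick(tree: RootedTree, lengths: bool = True, supports: bool = False) -> str:
    """Serialize canonically: children ordered by smallest descendant leaf label."""
    cache: dict[int, str] = {}

    def _fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            kids = sorted(node.children, key=lambda c: _min_leaf(c, cache))
            s = "(" + ",".join(_fmt(c) for c in kids) + ")"
            if supports and node.support is not None:
                s += format(node.support, "g")
            elif node.label:
                s += node.label
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return _fmt(tree.root) + ";"


def to_dendropy(tree: RootedTree, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=write_newick(tree),
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=taxon_namespace,
    )


def rf_distance(a: RootedTree, b: RootedTree) -> int:
    """Unrooted Robinson–Foulds distance (dendropy bipartition comparison)."""
    tns = dendropy.TaxonNamespace()
    da = to_dendropy(a, tns)
    db = to_dendropy(b, tns)
    da.encode_bipartitions()
    db.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(da, db)


def is_ultrametric(tree: RootedTree, tol: float = 1e-9) -> bool:
    """True when node heights are consistent: leaves at 0, parents above children."""
    for node in tree.postorder():
        h = node.height
        if h is None:
            return False
        if node.is_leaf and abs(h) > tol:
            return False
        for c in node.children:
            if c.height is None or c.height > h + tol:
                return False
    return True


def heights_to_lengths(tree: RootedTree) -> None:
    """Derive branch lengths from node heights (in place)."""
    for node in tree.preorder():
        if node.parent is not None and node.height is not None and node.parent.height is not None:
            node.length = node.parent.height - node.height
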