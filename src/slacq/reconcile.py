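"""Gene-tree/species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the lowest species-tree node containing all
species below it. An internal gene node is a duplication when its mapping
coincides with the mapping of one of its children; losses are counted per
gene-tree edge from the species-tree depth gap. Rooting of an unrooted gene
tree is chosen to minimize duplications + losses over all edge rootings, the
parsimony criterion used by reconciliation tools such as Notung.

Species trees must be binary; polytomies in the gene tree are rejected
rather than resolved (co-optimal polytomy resolution is an open extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .trees import Node, RootedTree, TreeError


class ReconcileError(ValueError):
    pass


SpeciesMap = dict[str, str]  # gene leaf label -> species leaf label


def species_node_label(node: Node, clades: dict[int, frozenset[str]]) -> str:
    """Stable label for a species-tree node: its name, or lca(...) of its leaves."""
    if node.is_leaf:
        return node.label or ""
    leaves = sorted(clades[id(node)])
    return "lca(" + ",".join(leaves) + ")"


@dataclass
class Reconciliation:
    node_map: dict[int, Node]  # id(gene node) -> species node
    duplication_nodes: list[Node]
    loss_count: int
    losses_per_edge: dict[int, int]  # id(gene child node) -> losses on its parent edge
    gene_tree: RootedTree
    species_tree: RootedTree

    @property
    def duplication_count(self) -> int:
        return len(self.duplication_nodes)

    @property
    def dl_cost(self) -> int:
        return self.duplication_count + self.loss_count


def _species_index(species: RootedTree):
    depths: dict[int, int] = {id(species.root): 0}
    parent: dict[int, Node] = {}
    for n in species.preorder():
        for c in n.children:
            depths[id(c)] = depths[id(n)] + 1
            parent[id(c)] = n
    return depths, parent


def _species_lca(a: Node, b: Node, depths: dict[int, int], parent: dict[int, Node]) -> Node:
    while a is not b:
        if depths[id(a)] < depths[id(b)]:
            b = parent[id(b)]
        elif depths[id(a)] > depths[id(b)]:
            a = parent[id(a)]
        else:
            a = parent[id(a)]
            b = parent[id(b)]
    return a


def lca_reconcile(gene: RootedTree, species: RootedTree, species_map: SpeciesMap) -> Reconciliation:
    """LCA reconciliation with duplication flags and per-edge loss counts.

    Losses on edge (v, c) = depth(M(c)) - depth(M(v)) - 1, plus 1 when v is a
    duplication whose mapping does not equal M(c) — each species-tree level
    skipped on the way down implies a lost copy in the sister lineage, and a
    duplication at M(v) followed by descent implies an extra loss of the other
    copy.
    """
    if not species.is_binary():
        raise ReconcileError("species tree must be binary")
    for n in gene.internal_nodes():
        if len(n.children) != 2:
            raise ReconcileError(
                "gene tree contains a polytomy; resolve it before reconciliation"
            )
    sp_leaves = {leaf.label: leaf for leaf in species.leaves()}
    depths, parent = _species_index(species)

    node_map: dict[int, Node] = {}
    duplications: list[Node] = []
    for node in gene.postorder():
        if node.is_leaf:
            if node.label not in species_map:
                raise ReconcileError(f"gene leaf {node.label!r} missing from species map")
            sp_label = species_map[node.label]
            if sp_label not in sp_leaves:
                raise ReconcileError(
                    f"species {sp_label!r} (gene leaf {node.label!r}) not in species tree"
                )
            node_map[id(node)] = sp_leaves[sp_label]
        else:
            m = node_map[id(node.children[0])]
            for c in node.children[1:]:
                m = _species_lca(m, node_map[id(c)], depths, parent)
            node_map[id(node)] = m
            if any(node_map[id(c)] is m for c in node.children):
                duplications.append(node)

    dup_ids = {id(n) for n in duplications}
    losses_per_edge: dict[int, int] = {}
    loss_count = 0
    for v in gene.internal_nodes():
        mv = node_map[id(v)]
        for c in v.children:
            mc = node_map[id(c)]
            gap = depths[id(mc)] - depths[id(mv)]
            losses = gap - 1
            if id(v) in dup_ids:
                # the copy produced at M(v) must survive down to M(c): every
                # level dropped, including the first, sheds a sister copy
                losses = gap
            losses = max(losses, 0)
            losses_per_edge[id(c)] = losses
            loss_count += losses
    return Reconciliation(
        node_map=node_map,
        duplication_nodes=duplications,
        loss_count=loss_count,
        losses_per_edge=losses_per_edge,
        gene_tree=gene,
        species_tree=species,
    )


# ---------------------------------------------------------------------------
# rooting by duplication+loss minimization

def _unrooted_edges(tree: RootedTree) -> list[tuple[Node, Node]]:
    """Edges of the unrooted topology as (parent, child) pairs of the given tree."""
    edges = []
    for n in tree.preorder():
        for c in n.children:
            edges.append((n, c))
    return edges


def _reroot_on_edge(tree: RootedTree, edge_child_path: list[int]) -> RootedTree:
    """Return a copy rooted on the edge above the node reached by ``edge_child_path``.

    ``edge_child_path`` is the child-index path from the root to the edge's
    child node.
    """
    work = tree.copy()
    node = work.root
    for idx in edge_child_path:
        node = node.children[idx]
    child = node
    parent = child.parent
    if parent is None:
        raise ReconcileError("cannot root above the root")
    # detach child; reverse the path from parent up to the old root
    parent.children.remove(child)
    child.parent = None
    path = []
    p: Node | None = parent
    while p is not None:
        path.append(p)
        p = p.parent
    # reverse parent links along path: path[0] (=parent) becomes a child chain
    for lower, upper in zip(path, path[1:]):
        upper.children.remove(lower)
        upper.parent = None
        lower.add_child(upper)
    new_root = Node()
    new_root.add_child(child)
    new_root.add_child(parent)
    work2 = RootedTree(root=new_root)
    _suppress_unifurcations(work2)
    return work2


def _suppress_unifurcations(tree: RootedTree) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if not node.is_leaf and len(node.children) == 1:
                child = node.children[0]
                if node.parent is None:
                    child.parent = None
                    tree.root = child
                else:
                    p = node.parent
                    i = p.children.index(node)
                    p.children[i] = child
                    child.parent = p
                changed = True
                break


def root_min_dl(
    gene_unrooted: RootedTree,
    species: RootedTree,
    species_map: SpeciesMap,
) -> list[tuple[RootedTree, Reconciliation]]:
    """Evaluate every edge as a root position; return all co-optimal rootings.

    The input tree's current root is treated as arbitrary (an unrooted tree
    read from Newick typically has a trifurcating root). Results are ordered
    canonically by the Newick string of the rooted topology.
    """
    if len(gene_unrooted.leaves()) < 3:
        raise ReconcileError("need >= 3 leaves to root by reconciliation")

    # enumerate edges by child-index paths so they survive tree copying
    paths: list[list[int]] = []

    def _walk(node: Node, path: list[int]) -> None:
        for i, c in enumerate(node.children):
            paths.append(path + [i])
            _walk(c, path + [i])

    _walk(gene_unrooted.root, [])

    from .trees import write_newick  # local import to avoid cycle at module load

    best_cost: int | None = None
    results: dict[str, tuple[RootedTree, Reconciliation]] = {}
    for path in paths:
        try:
            rooted = _reroot_on_edge(gene_unrooted, path)
        except ReconcileError:
            continue
        rec = lca_reconcile(rooted, species, species_map)
        cost = rec.dl_cost
        key = write_newick(rooted, lengths=False)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            results = {key: (rooted, rec)}
        elif cost == best_cost and key not in results:
            results[key] = (rooted, rec)
    return [results[k] for k in sorted(results)]


# ---------------------------------------------------------------------------
# duplication-event narrative

@dataclass(frozen=True)
class DuplicationEvent:
    species_node: str  # label of the species-tree node where the event maps
    side_a: tuple[str, ...]  # leaf groups (or labels) separated by the event
    side_b: tuple[str, ...]


def annotate_duplication_history(
    rec: Reconciliation,
    ortholog_group_labels: dict[str, str] | None = None,
) -> list[DuplicationEvent]:
    """One row per duplication: where it maps on the species tree and which
    descendant leaf-group partition it separates.

    ``ortholog_group_labels`` maps gene leaf labels to group names; leaves
    without an entry are reported by their own label. The table is invariant
    to gene-tree child order.
    """
    sp_clades = rec.species_tree.clades()
    gene_clades = rec.gene_tree.clades()
    labels = ortholog_group_labels or {}

    def _side(node: Node) -> tuple[str, ...]:
        groups = {labels.get(l, l) for l in gene_clades[id(node)]}
        return tuple(sorted(groups))

    events = []
    for v in rec.duplication_nodes:
        sides = sorted(_side(c) for c in v.children)
        events.append(DuplicationEvent(
            species_node=species_node_label(rec.node_map[id(v)], sp_clades),
            side_a=sides[0],
            side_b=sides[1],
        ))
    events.sort(key=lambda e: (e.species_node, e.side_a, e.side_b))
    return events


def write_reconciliation_report(rec: Reconciliation, path: str | Path) -> None:
    sp_clades = rec.species_tree.clades()
    gene_clades = rec.gene_tree.clades()
    dup_ids = {id(n) for n in rec.duplication_nodes}
    with open(path, "w") as fh:
        fh.write("node_id\tmapped_species_node\tis_duplication\tlosses_on_parent_edge\n")
        for node in rec.gene_tree.postorder():
            if node.is_leaf:
                nid = node.label
            else:
                nid = "lca(" + ",".join(sorted(gene_clades[id(node)])) + ")"
            fh.write(
                f"{nid}\t{species_node_label(rec.node_map[id(node)], sp_clades)}"
                f"\t{int(id(node) in dup_ids)}"
                f"\t{rec.losses_per_edge.get(id(node), 0)}\n"
            )
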