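"""Identity-based grouping: UPGMA clustering, robust blocks, group statistics,
bootstrap support, and conservation-zone segmentation.

The phylogenetic engine here is deliberately distance-based: channels are
hierarchically clustered on pairwise percent identities with UPGMA, which
yields an ultrametric tree whose merge heights are half the average
distances. Maximum-likelihood inference is out of scope; externally produced
ML trees can be supplied as Newick for reconciliation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curation import ScoringConfig, global_identity
from .sequences import GAP, MultipleAlignment, ProteinSequence
from .trees import Node, RootedTree, heights_to_lengths


class GroupingError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise GroupingError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise GroupingError("distance matrix must be symmetric")
        if not np.all(np.diag(self.matrix) == 0):
            raise GroupingError("distance matrix diagonal must be exactly 0")
        if (self.matrix < 0).any():
            raise GroupingError("distances must be non-negative")


def pairwise_identity_aligned(row_a: str, row_b: str) -> float:
    """Percent identity over columns where not both rows are gapped."""
    used = 0
    matches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            continue
        used += 1
        if x == y and x != GAP and x != "X":
            matches += 1
    if used == 0:
        return 0.0
    return 100.0 * matches / used


def identity_distance_matrix(
    data: MultipleAlignment | list[ProteinSequence],
    scoring_config: ScoringConfig | None = None,
) -> DistanceMatrix:
    """Distance = 100 - percent identity.

    Aligned input uses column-wise identity over shared non-double-gap
    columns; unaligned input uses pairwise global alignment.
    """
    if isinstance(data, MultipleAlignment):
        ids = data.ids
        rows = [row for _, row in data.records]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pid = pairwise_identity_aligned(rows[i], rows[j])
                d[i, j] = d[j, i] = 100.0 - pid
    else:
        if len(data) < 2:
            raise GroupingError("need at least 2 sequences")
        ids = [s.id for s in data]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pid = global_identity(data[i], data[j], scoring_config)
                d[i, j] = d[j, i] = 100.0 - pid
    return DistanceMatrix(ids=ids, matrix=d)


def upgma(D: DistanceMatrix) -> RootedTree:
    """UPGMA with size-weighted average linkage and merge height d/2.

    Ties are broken toward the lowest (i, j) index pair, so the builder is
    fully deterministic for a given input order.
    """
    n = len(D.ids)
    if n < 2:
        raise GroupingError("need at least 2 taxa")
    nodes: dict[int, Node] = {
        i: Node(label=D.ids[i], height=0.0) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.matrix[i, j])
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                d = dist[(i, j)]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best  # type: ignore[misc]
        parent = Node(height=d / 2.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        active.append(next_id)
        next_id += 1
    tree = RootedTree(root=nodes[active[0]])
    heights_to_lengths(tree)
    return tree


def cut_to_clusters(tree: RootedTree, k: int) -> dict[str, int]:
    """Cut an ultrametric tree at the height giving exactly ``k`` clusters.

    Returns leaf label -> cluster index (0-based, in order of first leaf).
    """
    nodes = sorted(tree.internal_nodes(), key=lambda n: -(n.height or 0.0))
    clusters: list[Node] = [tree.root]
    for node in nodes:
        if len(clusters) >= k:
            break
        if node in clusters:
            clusters.remove(node)
            clusters.extend(node.children)
    clades = tree.clades()
    assignment: dict[str, int] = {}
    ordered = sorted(clusters, key=lambda c: min(clades[id(c)]))
    for ci, c in enumerate(ordered):
        for leaf in clades[id(c)]:
            assignment[leaf] = ci
    return assignment


# ---------------------------------------------------------------------------
# robust blocks (transparent two-rule stand-in for robust-region selection)

@dataclass(frozen=True)
class Block:
    start_col: int  # 1-based inclusive
    end_col: int


def modal_residue_fraction(column: str) -> float:
    """Fraction of rows carrying the most common non-gap residue."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return 0.0
    return max(counts.values()) / len(column)


def conserved_blocks(
    aln: MultipleAlignment,
    min_ident_frac: float = 0.5,
    min_block_len: int = 5,
    max_gap_frac: float = 0.5,
) -> list[Block]:
    """Maximal runs of conserved, gap-poor columns.

    A column is good iff its modal-residue fraction is >= ``min_ident_frac``
    and its gap fraction is <= ``max_gap_frac``; blocks are maximal good runs
    of length >= ``min_block_len``.
    """
    good = []
    for c in range(aln.ncol):
        col = aln.column(c)
        gap_frac = col.count(GAP) / len(col)
        good.append(
            modal_residue_fraction(col) >= min_ident_frac
            and gap_frac <= max_gap_frac
        )
    blocks: list[Block] = []
    start = None
    for c, g in enumerate(good + [False]):
        if g and start is None:
            start = c
        elif not g and start is not None:
            if c - start >= min_block_len:
                blocks.append(Block(start_col=start + 1, end_col=c))
            start = None
    return blocks


# ---------------------------------------------------------------------------
# within/between group identity statistics

@dataclass
class IdentityStats:
    mean: float
    sd: float  # population SD over pairs
    min: float
    max: float
    n_pairs: int


@dataclass
class GroupIdentityStats:
    within: dict[str, IdentityStats | None]  # None for singleton groups
    between: dict[tuple[str, str], IdentityStats]


def _stats(values: list[float]) -> IdentityStats:
    arr = np.asarray(values, float)
    return IdentityStats(
        mean=float(arr.mean()),
        sd=float(arr.std()),  # population convention
        min=float(arr.min()),
        max=float(arr.max()),
        n_pairs=len(values),
    )


def group_identity_stats(
    data: MultipleAlignment | list[ProteinSequence],
    group_assignment: dict[str, str],
    scoring_config: ScoringConfig | None = None,
) -> GroupIdentityStats:
    """Mean/SD/min/max percent identity within each group and between group pairs."""
    D = identity_distance_matrix(data, scoring_config)
    idx = {sid: i for i, sid in enumerate(D.ids)}
    identity = 100.0 - D.matrix
    groups: dict[str, list[str]] = {}
    for sid, g in group_assignment.items():
        if sid in idx:
            groups.setdefault(g, []).append(sid)
    within: dict[str, IdentityStats | None] = {}
    for g, members in groups.items():
        if len(members) < 2:
            within[g] = None  # singleton: within-group stats undefined
            continue
        vals = [
            identity[idx[a], idx[b]]
            for a, b in itertools.combinations(members, 2)
        ]
        within[g] = _stats(vals)
    between: dict[tuple[str, str], IdentityStats] = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        vals = [
            identity[idx[a], idx[b]]
            for a in groups[ga]
            for b in groups[gb]
        ]
        between[(ga, gb)] = _stats(vals)
    return GroupIdentityStats(within=within, between=between)


# ---------------------------------------------------------------------------
# bootstrap support on the UPGMA builder

def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
) -> RootedTree:
    """Column-resampling bootstrap support for the UPGMA tree.

    Columns are resampled with replacement; each replicate alignment is
    re-clustered and the support of each internal clade of the reference
    tree is the fraction of replicate trees containing the same clade.
    """
    if n_reps < 1:
        raise GroupingError("n_reps must be >= 1")
    ref_tree = upgma(identity_distance_matrix(aln))
    ref_clades = ref_tree.clades()
    counts: dict[frozenset[str], int] = {
        ref_clades[id(n)]: 0 for n in ref_tree.internal_nodes()
    }
    rng = np.random.default_rng(seed)
    ncol = aln.ncol
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        records = [
            (rid, "".join(row[c] for c in cols)) for rid, row in aln.records
        ]
        try:
            rep_aln = MultipleAlignment(records=records)
        except Exception:
            continue  # a resample can make a row all-gap; replicate dropped
        rep_tree = upgma(identity_distance_matrix(rep_aln))
        rep_clades = {
            rep_tree.clades()[id(n)] for n in rep_tree.internal_nodes()
        }
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in ref_tree.internal_nodes():
        node.support = counts[ref_clades[id(node)]] / n_reps
    return ref_tree


# ---------------------------------------------------------------------------
# conservation-zone segmentation

@dataclass(frozen=True)
class Zone:
    start_col: int  # 1-based inclusive
    end_col: int
    mean_identity: float  # mean smoothed modal-residue fraction, percent
    label: str  # "high" | "low"


def conservation_zones(
    aln: MultipleAlignment,
    window: int = 11,
    threshold: float = 0.5,
) -> list[Zone]:
    """Alternating high/low conservation zones of a region alignment.

    Per-column modal-residue fractions are smoothed with a centered moving
    average of width ``window`` (truncated at the edges); zones are maximal
    runs above/below ``threshold``, with adjacent same-label runs merged, so
    labels strictly alternate.
    """
    if window < 1:
        raise GroupingError("window must be >= 1")
    raw = np.array([modal_residue_fraction(aln.column(c)) for c in range(aln.ncol)])
    half = window // 2
    smoothed = np.array([
        raw[max(0, c - half) : min(len(raw), c + half + 1)].mean()
        for c in range(len(raw))
    ])
    labels = ["high" if v >= threshold else "low" for v in smoothed]
    zones: list[Zone] = []
    start = 0
    for c in range(1, len(labels) + 1):
        if c == len(labels) or labels[c] != labels[start]:
            zones.append(Zone(
                start_col=start + 1,
                end_col=c,
                mean_identity=float(100.0 * smoothed[start:c].mean()),
                label=labels[start],
            ))
            start = c
    return zones


# ---------------------------------------------------------------------------
# TSV export

def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for i, rid in enumerate(D.ids):
            fh.write(rid + "\t" + "\t".join(f"{x:.4f}" for x in D.matrix[i]) + "\n")


def write_zone_report(zones: list[Zone], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_col\tend_col\tlabel\tmean_identity\n")
        for z in zones:
            fh.write(f"{z.start_col}\t{z.end_col}\t{z.label}\t{z.mean_identity:.2f}\n")


def write_block_report(blocks: list[Block], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_col\tend_col\n")
        for b in blocks:
            fh.write(f"{b.start_col}\t{b.end_col}\n")
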