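"""Synthetic protein-family generator with known ground truth.

Everything downstream of proteome download in the real analysis is exercised
here against families whose true trees, events, domain architecture, and
planted regulatory sites are known:

* a Yule species tree;
* a gene family evolving along it by duplication and loss, every event
  recorded with its species-tree location;
* sequences with a fixed domain architecture — cytosolic termini and
  linkers, hydrophobic transmembrane (TM) segments, conserved motif
  regions, a WEP-like anchor triplet — evolved by per-site Poisson
  replacement draws from region-specific compositions;
* divergence tiers calibrated analytically so that realized within-group
  identities sit near 78/69/58% and between-group identities near 35–52%,
  the regime observed for the three angiosperm SLAC-like channel groups;
* group-specifically conserved Ser/Thr sites planted in a basophilic
  context that the surrogate phosphosite scorer recognizes.

v1 is indel-free, so the true alignment is the trivial column map and every
planted feature has fixed alignment coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .sequences import (
    AMINO_ACIDS,
    MultipleAlignment,
    ProteinSequence,
    write_alignment_fasta,
    write_fasta,
    write_species_map,
)
from .trees import Node, RootedTree, heights_to_lengths, write_newick

AA = np.array(list(AMINO_ACIDS))
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SimulationError(ValueError):
    pass


class EmptyFamilyError(SimulationError):
    """All gene lineages were lost; the caller should retry with a new seed."""


# ---------------------------------------------------------------------------
# residue compositions

def _comp(d: dict[str, float]) -> np.ndarray:
    v = np.zeros(20)
    for a, p in d.items():
        v[AA_INDEX[a]] = p
    if not np.isclose(v.sum(), 1.0):
        raise SimulationError("composition must sum to 1")
    return v


#: hydrophobic-biased TM composition (Kyte–Doolittle mean ~ +2.8)
COMP_TM = _comp({
    "I": 0.18, "L": 0.18, "V": 0.15, "F": 0.12, "A": 0.12, "M": 0.07,
    "C": 0.04, "G": 0.06, "T": 0.04, "S": 0.04,
})
#: neutral linker/terminus composition (KD mean ~ -0.6)
COMP_NEUTRAL = _comp({
    "A": 0.07, "R": 0.06, "N": 0.05, "D": 0.06, "C": 0.01, "Q": 0.05,
    "E": 0.07, "G": 0.07, "H": 0.02, "I": 0.04, "L": 0.08, "K": 0.07,
    "M": 0.02, "F": 0.04, "P": 0.06, "S": 0.08, "T": 0.06, "W": 0.01,
    "Y": 0.03, "V": 0.05,
})
#: global background for decoy sequences
COMP_BACKGROUND = np.full(20, 1.0 / 20)

COMPOSITIONS = {"tm": COMP_TM, "neutral": COMP_NEUTRAL, "background": COMP_BACKGROUND}


# ---------------------------------------------------------------------------
# architecture

#: planted-site context written around each acceptor (acceptor at the dot);
#: matches the surrogate scorer's basophilic consensus
SITE_CONTEXT = "KRRQ.GPEE"
NON_CARRIER_RESIDUE = "A"


@dataclass(frozen=True)
class PlantedSite:
    offset: int  # 0-based offset of the acceptor within its region
    carriers: tuple[str, ...]  # group names carrying the conserved site
    acceptor: str = "S"  # S, T, or Y


@dataclass(frozen=True)
class Region:
    name: str
    length: int
    composition: str  # key into COMPOSITIONS
    rate_mult: float
    is_tm: bool = False
    is_motif: bool = False  # used as an HMM seed/screen fingerprint region
    fixed: tuple[tuple[int, str], ...] = ()  # (offset, residue) anchors, rate 0
    sites: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationError(f"region {self.name}: length must be >= 1")
        if self.rate_mult < 0:
            raise SimulationError(f"region {self.name}: rate must be >= 0")


def slac_architecture() -> list[Region]:
    """SLAC-like: long cytosolic N-terminus, 10 TMs (odd TMs are the motif
    fingerprints), cytosolic C-terminus; planted group-specific phosphosites
    in the N-terminus, one inter-TM linker, and the proximal C-terminus."""
    regions: list[Region] = [
        Region("nterm", 90, "neutral", 1.0, sites=(
            PlantedSite(20, ("tier1",)),
            PlantedSite(50, ("tier1", "tier2")),
            PlantedSite(75, ("tier2",), acceptor="T"),
        )),
    ]
    for i in range(1, 11):
        motif = i % 2 == 1
        regions.append(Region(
            f"tm{i}", 21, "tm", 0.25 if motif else 0.6,
            is_tm=True, is_motif=motif,
        ))
        if i < 10:
            sites = (PlantedSite(7, ("tier2", "tier3")),) if i == 4 else ()
            regions.append(Region(f"loop{i}", 15, "neutral", 1.5, sites=sites))
    regions.append(Region("cterm", 40, "neutral", 1.0, sites=(
        PlantedSite(6, ("tier1", "tier2"), acceptor="T"),
    )))
    return regions


def almt_architecture() -> list[Region]:
    """ALMT/QUAC-like: 6 N-half TMs, then a C-terminal half with alternating
    conservation zones, a WEP anchor followed by a hydrophobic segment (TM7)
    and a second hydrophobic cluster (TM8)."""
    regions: list[Region] = [Region("nterm", 40, "neutral", 1.2)]
    for i in range(1, 7):
        regions.append(Region(
            f"tm{i}", 21, "tm", 0.5, is_tm=True, is_motif=i in (1, 4),
        ))
        if i < 6:
            regions.append(Region(f"loop{i}", 15, "neutral", 1.5))
    regions += [
        Region("clink", 20, "neutral", 1.5),
        Region("zone1", 15, "neutral", 0.3),
        Region("zone2", 15, "neutral", 2.0),
        Region("zone3_wep", 15, "neutral", 0.3,
               fixed=((6, "W"), (7, "E"), (8, "P"))),
        Region("tm7", 21, "tm", 0.5, is_tm=True),
        Region("zone6", 15, "neutral", 2.0),
        Region("zone7", 15, "neutral", 0.3),
        Region("zone8", 15, "neutral", 2.0),
        Region("tm8", 21, "tm", 0.5, is_tm=True),
        Region("cterm", 30, "neutral", 1.5),
    ]
    return regions


@dataclass
class FamilyConfig:
    """Study conditions for one synthetic benchmark family."""

    family: str = "slac"  # "slac" | "almt"
    n_species: int = 10
    birth_rate: float = 1.0
    n_decoys: int = 5
    #: target mean within-group identities, percent (youngest to oldest tier)
    within_identity: tuple[float, ...] = (78.0, 69.0, 58.0)
    #: target identities between (tier1, tier2) and across the family root
    between_identity_close: float = 52.0
    between_identity_far: float = 35.5
    #: fraction of the species-tree height variation retained inside each
    #: tier subtree. Ortholog groups radiate quickly relative to the ancient
    #: duplications separating them, so within-group coalescent heights are
    #: compressed toward the group crown; 1.0 reproduces the species-tree
    #: shape exactly, 0.0 a star
    crown_spread: float = 0.2
    dup_rate: float = 0.0  # free-standing duplication/loss benchmarks only
    loss_rate: float = 0.0
    seed: int = 0

    @property
    def architecture(self) -> list[Region]:
        if self.family == "slac":
            return slac_architecture()
        if self.family == "almt":
            return almt_architecture()
        raise SimulationError(f"unknown family preset: {self.family!r}")

    @property
    def group_names(self) -> list[str]:
        return [f"tier{i + 1}" for i in range(len(self.within_identity))]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_species": self.n_species,
            "birth_rate": self.birth_rate,
            "n_decoys": self.n_decoys,
            "within_identity": list(self.within_identity),
            "between_identity_close": self.between_identity_close,
            "between_identity_far": self.between_identity_far,
            "crown_spread": self.crown_spread,
            "dup_rate": self.dup_rate,
            "loss_rate": self.loss_rate,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# species tree (Yule)

def yule_leaf_count(birth_rate: float, duration: float, rng: np.random.Generator) -> int:
    """Leaf count of an unconstrained pure-birth process run for ``duration``."""
    n = 1
    t = 0.0
    while True:
        t += rng.exponential(1.0 / (birth_rate * n))
        if t > duration:
            return n
        n += 1


def simulate_species_tree(
    n_species: int,
    seed: int,
    birth_rate: float = 1.0,
    normalize_depth: bool = True,
) -> RootedTree:
    """Pure-birth (Yule) tree on ``n_species`` extant tips, ultrametric.

    With ``normalize_depth`` the root-to-leaf depth is rescaled to 1, which
    makes divergence-tier scaling factors directly interpretable.
    """
    if n_species < 2:
        raise SimulationError("need n_species >= 2")
    rng = np.random.default_rng(seed)
    root = Node()
    active = [root]
    t = 0.0
    birth_times = {id(root): 0.0}
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        for _ in range(2):
            child = Node()
            node.add_child(child)
            birth_times[id(child)] = t
            active.append(child)
    # one final waiting time so the last split is not at the leaves
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.label = f"S{i + 1:02d}"
    tree = RootedTree(root=root)
    for node in tree.postorder():
        if node.is_leaf:
            node.height = 0.0
        else:
            node.height = t - birth_times[id(node.children[0])]
    if normalize_depth and tree.root.height:
        scale = 1.0 / tree.root.height
        for node in tree.postorder():
            node.height = (node.height or 0.0) * scale
    heights_to_lengths(tree)
    return tree


# ---------------------------------------------------------------------------
# gene family birth-death along the species tree

@dataclass(frozen=True)
class GeneEvent:
    kind: str  # "duplication" | "loss"
    species_edge: str  # label of the species node below the edge
    time: float  # absolute time from the species root


def simulate_gene_family(
    species_tree: RootedTree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
) -> tuple[RootedTree, list[GeneEvent], dict[str, str]]:
    """Evolve a gene family along the species tree by duplication and loss.

    Returns the surviving-leaf gene tree, the full event list (including
    events on extinct sublineages), and the gene-leaf -> species map. Raises
    :class:`EmptyFamilyError` when no lineage survives.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise SimulationError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    events: list[GeneEvent] = []
    counters: dict[str, int] = {}
    sp_depth_time: dict[int, float] = {}
    for n in species_tree.preorder():
        if n.parent is None:
            sp_depth_time[id(n)] = 0.0
        else:
            sp_depth_time[id(n)] = sp_depth_time[id(n.parent)] + (n.length or 0.0)

    total_rate = dup_rate + loss_rate

    def species_label(node: Node) -> str:
        if node.label:
            return node.label
        leaves = sorted(
            l.label for l in RootedTree(root=node).leaves() if l.label
        )
        return "lca(" + ",".join(leaves) + ")"

    def evolve_edge(sp_child: Node, t_remaining: float, t_abs: float) -> Node | None:
        if total_rate > 0:
            dt = rng.exponential(1.0 / total_rate)
        else:
            dt = np.inf
        if dt < t_remaining:
            t_event = t_abs + dt
            if rng.random() < dup_rate / total_rate:
                events.append(GeneEvent("duplication", species_label(sp_child), t_event))
                left = evolve_edge(sp_child, t_remaining - dt, t_event)
                right = evolve_edge(sp_child, t_remaining - dt, t_event)
                surviving = [x for x in (left, right) if x is not None]
                if len(surviving) == 2:
                    node = Node()
                    node.time = t_event  # type: ignore[attr-defined]
                    for s in surviving:
                        node.add_child(s)
                    return node
                return surviving[0] if surviving else None
            events.append(GeneEvent("loss", species_label(sp_child), t_event))
            return None
        t_arrive = t_abs + t_remaining
        if sp_child.is_leaf:
            counters[sp_child.label] = counters.get(sp_child.label, 0) + 1  # type: ignore[index]
            leaf = Node(label=f"{sp_child.label}_g{counters[sp_child.label]}")
            leaf.time = t_arrive  # type: ignore[attr-defined]
            return leaf
        kids = [
            evolve_edge(c, c.length or 0.0, t_arrive) for c in sp_child.children
        ]
        surviving = [k for k in kids if k is not None]
        if len(surviving) >= 2:
            node = Node()
            node.time = t_arrive  # type: ignore[attr-defined]
            for s in surviving:
                node.add_child(s)
            return node
        return surviving[0] if surviving else None

    sp_root = species_tree.root
    kids = [evolve_edge(c, c.length or 0.0, 0.0) for c in sp_root.children]
    surviving = [k for k in kids if k is not None]
    if not surviving:
        raise EmptyFamilyError("all gene lineages were lost")
    if len(surviving) == 1:
        root = surviving[0]
    else:
        root = Node()
        root.time = 0.0  # type: ignore[attr-defined]
        for s in surviving:
            root.add_child(s)
    gene_tree = RootedTree(root=root)
    root_time = getattr(root, "time", 0.0)
    for node in gene_tree.preorder():
        if node.parent is not None:
            node.length = getattr(node, "time") - getattr(node.parent, "time")
    # heights for downstream consumers
    max_time = max(getattr(l, "time") for l in gene_tree.leaves())
    for node in gene_tree.postorder():
        node.height = max_time - getattr(node, "time", root_time)
    species_map = {
        leaf.label: leaf.label.rsplit("_g", 1)[0] for leaf in gene_tree.leaves()
    }
    return gene_tree, events, species_map


def true_duplication_count(events: list[GeneEvent]) -> int:
    return sum(1 for e in events if e.kind == "duplication")


# ---------------------------------------------------------------------------
# sequence evolution

def _site_arrays(arch: list[Region]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site rate multipliers and composition indices (row into comp table)."""
    comp_keys = list(COMPOSITIONS)
    rates = []
    comp_idx = []
    for region in arch:
        r = np.full(region.length, region.rate_mult)
        for off, _res in region.fixed:
            r[off] = 0.0
        for site in region.sites:
            for off in range(site.offset - 4, site.offset + 5):
                if 0 <= off < region.length:
                    r[off] = 0.0
        rates.append(r)
        comp_idx.append(np.full(region.length, comp_keys.index(region.composition)))
    return np.concatenate(rates), np.concatenate(comp_idx)


def _root_sequence(arch: list[Region], rng: np.random.Generator) -> np.ndarray:
    parts = []
    for region in arch:
        comp = COMPOSITIONS[region.composition]
        idx = rng.choice(20, size=region.length, p=comp)
        for off, res in region.fixed:
            idx[off] = AA_INDEX[res]
        for site in region.sites:
            context = SITE_CONTEXT.replace(".", site.acceptor)
            for k, ch in enumerate(context, start=site.offset - 4):
                if 0 <= k < region.length:
                    idx[k] = AA_INDEX[ch]
        parts.append(idx)
    return np.concatenate(parts)


def _evolve(seq: np.ndarray, branch: float, rates: np.ndarray,
            comp_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Poisson-replacement step: each site substitutes with probability
    1 - exp(-rate * branch); replacements are fresh draws from the site's
    region composition (which may re-draw the same residue)."""
    out = seq.copy()
    p_sub = 1.0 - np.exp(-rates * branch)
    hit = rng.random(len(seq)) < p_sub
    comp_keys = list(COMPOSITIONS)
    for key_i, key in enumerate(comp_keys):
        sel = hit & (comp_idx == key_i)
        k = int(sel.sum())
        if k:
            out[sel] = rng.choice(20, size=k, p=COMPOSITIONS[key])
    return out


def _seq_to_str(idx: np.ndarray) -> str:
    return "".join(AA[idx])


def expected_identity(pathlen: float, rates: np.ndarray, comp_idx: np.ndarray) -> float:
    """Expected fraction of matching sites between two sequences separated by
    total path length ``pathlen`` under the replacement-draw model:
    per site, exp(-r*pathlen) + (1 - exp(-r*pathlen)) * sum(p_a^2)."""
    comp_keys = list(COMPOSITIONS)
    kappa = np.array([float((COMPOSITIONS[k] ** 2).sum()) for k in comp_keys])
    q2 = np.exp(-rates * pathlen)
    site_kappa = kappa[comp_idx]
    return float(np.mean(q2 + (1.0 - q2) * site_kappa))


def solve_pathlen_for_identity(target_pct: float, rates: np.ndarray,
                               comp_idx: np.ndarray) -> float:
    """Invert the expected-identity curve for a total path length."""
    target = target_pct / 100.0
    floor = expected_identity(200.0, rates, comp_idx)
    if target <= floor:
        raise SimulationError(
            f"target identity {target_pct}% is below the compositional floor "
            f"({100 * floor:.1f}%)"
        )
    return float(brentq(
        lambda t: expected_identity(t, rates, comp_idx) - target, 0.0, 200.0,
        xtol=1e-10,
    ))


# ---------------------------------------------------------------------------
# the tier benchmark bundle

@dataclass
class TruthBundle:
    config: FamilyConfig
    species_tree: RootedTree
    gene_tree: RootedTree
    sequences: list[ProteinSequence]  # family members
    decoys: list[ProteinSequence]
    alignment: MultipleAlignment  # trivial (indel-free) true alignment, members only
    groups: dict[str, str]  # seq_id -> tier name
    species_map: dict[str, str]  # seq_id -> species label
    tm_intervals: list[tuple[int, int]]  # 1-based alignment columns
    motif_regions: dict[str, tuple[int, int]]  # motif name -> columns
    planted_site_columns: list[tuple[str, int]]  # (group, 1-based column)
    manifest: dict

    def region_columns(self) -> dict[str, tuple[int, int]]:
        out = {}
        start = 1
        for region in self.config.architecture:
            out[region.name] = (start, start + region.length - 1)
            start += region.length
        return out


def _pairwise_heights(tree: RootedTree) -> list[float]:
    """MRCA heights of all leaf pairs of an ultrametric tree."""
    clades = tree.clades()
    leaves = tree.leaf_labels()
    heights = []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            pair = {leaves[i], leaves[j]}
            best = None
            for node in tree.postorder():
                if pair <= clades[id(node)]:
                    if best is None or (node.height or 0) < best:
                        best = node.height or 0
            heights.append(float(best))
    return heights


def _solve_tier_scale(target_pct: float, heights: list[float],
                      rates: np.ndarray, comp_idx: np.ndarray) -> float:
    """Scale s such that the mean over leaf pairs of expected identity at
    path 2*s*h equals the tier target."""
    def mean_identity(s: float) -> float:
        return float(np.mean([
            expected_identity(2.0 * s * h, rates, comp_idx) for h in heights
        ]))

    lo, hi = 1e-6, 200.0
    if mean_identity(lo) < target_pct / 100.0:
        raise SimulationError("tier target identity unreachable (too high)")
    return float(brentq(lambda s: mean_identity(s) - target_pct / 100.0, lo, hi,
                        xtol=1e-10))


def make_benchmark(config: FamilyConfig) -> TruthBundle:
    """Generate one benchmark family under the configured study conditions.

    The gene tree is three copies of the species tree (two ancient
    duplications, no losses), one per divergence tier, with branch lengths
    scaled per tier so the expected within-group identities hit the
    configured targets; the two duplication heights are solved the same way
    from the between-group targets.
    """
    arch = config.architecture
    rates, comp_idx = _site_arrays(arch)
    rng = np.random.default_rng(config.seed)

    species = simulate_species_tree(config.n_species, seed=int(rng.integers(2**31)),
                                    birth_rate=config.birth_rate)
    spread = config.crown_spread
    heights = [
        1.0 - spread * (1.0 - h) for h in _pairwise_heights(species)
    ]

    scales = [
        _solve_tier_scale(t, heights, rates, comp_idx)
        for t in config.within_identity
    ]
    path_close = solve_pathlen_for_identity(config.between_identity_close, rates, comp_idx)
    path_far = solve_pathlen_for_identity(config.between_identity_far, rates, comp_idx)
    h_close = path_close / 2.0
    h_root = path_far / 2.0
    if h_close <= max(scales[:2]) or h_root <= h_close:
        raise SimulationError(
            "between-group identity targets are not below the within-group "
            "targets; duplication heights would be inconsistent"
        )

    groups = config.group_names

    def tier_copy(tier: str, scale: float) -> Node:
        sub = species.copy()
        for node in sub.postorder():
            if node.is_leaf:
                node.height = 0.0
                node.label = f"{tier}_{node.label}"
            else:
                node.height = scale * (1.0 - spread * (1.0 - (node.height or 0.0)))
        return sub.root

    # gene tree: ((tier1, tier2) at h_close, tier3) at h_root
    n12 = Node(height=h_close)
    n12.add_child(tier_copy(groups[0], scales[0]))
    n12.add_child(tier_copy(groups[1], scales[1]))
    root = Node(height=h_root)
    root.add_child(n12)
    root.add_child(tier_copy(groups[2], scales[2]))
    gene_tree = RootedTree(root=root)
    heights_to_lengths(gene_tree)

    # evolve sequences down the gene tree
    root_seq = _root_sequence(arch, rng)
    site_truth = _planted_site_positions(arch)
    group_of_leaf: dict[str, str] = {}
    seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray, tier: str | None) -> None:
        for child in node.children:
            child_tier = tier
            child_seq = _evolve(seq, child.length or 0.0, rates, comp_idx, rng)
            # entering a tier subtree: force planted-site acceptors
            leaf_labels = [l.label or "" for l in RootedTree(root=child).leaves()]
            tiers_below = {l.split("_", 1)[0] for l in leaf_labels}
            if child_tier is None and len(tiers_below) == 1:
                child_tier = tiers_below.pop()
                child_seq = child_seq.copy()
                for site, pos0 in site_truth:
                    if child_tier in site.carriers:
                        child_seq[pos0] = AA_INDEX[site.acceptor]
                    else:
                        child_seq[pos0] = AA_INDEX[NON_CARRIER_RESIDUE]
            if child.is_leaf:
                label = child.label or ""
                seqs[label] = child_seq
                group_of_leaf[label] = label.split("_", 1)[0]
            else:
                walk(child, child_seq, child_tier)

    walk(gene_tree.root, root_seq, None)

    member_ids = sorted(seqs)
    members = [
        ProteinSequence(id=sid, residues=_seq_to_str(seqs[sid]),
                        species=sid.split("_", 1)[1])
        for sid in member_ids
    ]
    total_len = int(rates.shape[0])
    decoys = [
        ProteinSequence(
            id=f"decoy{i + 1}",
            residues=_seq_to_str(rng.choice(20, size=total_len, p=COMP_BACKGROUND)),
        )
        for i in range(config.n_decoys)
    ]
    alignment = MultipleAlignment(records=[(s.id, s.residues) for s in members])

    # truth coordinates (1-based alignment columns; indel-free)
    region_cols: dict[str, tuple[int, int]] = {}
    start = 1
    for region in arch:
        region_cols[region.name] = (start, start + region.length - 1)
        start += region.length
    tm_intervals = [region_cols[r.name] for r in arch if r.is_tm]
    motif_regions = {r.name: region_cols[r.name] for r in arch if r.is_motif}
    site_columns = sorted(
        (tier, pos0 + 1)
        for site, pos0 in site_truth
        for tier in site.carriers
    )

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "generator": "slacq.synth/1",
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_members": len(members),
        "n_decoys": len(decoys),
        "sequence_length": total_len,
        "tier_scales": [round(s, 10) for s in scales],
        "duplication_heights": [round(h_close, 10), round(h_root, 10)],
    }
    species_map = {s.id: s.species or "" for s in members}
    return TruthBundle(
        config=config,
        species_tree=species,
        gene_tree=gene_tree,
        sequences=members,
        decoys=decoys,
        alignment=alignment,
        groups=group_of_leaf,
        species_map=species_map,
        tm_intervals=tm_intervals,
        motif_regions=motif_regions,
        planted_site_columns=site_columns,
        manifest=manifest,
    )


def _planted_site_positions(arch: list[Region]) -> list[tuple[PlantedSite, int]]:
    out = []
    start = 0
    for region in arch:
        for site in region.sites:
            out.append((site, start + site.offset))
        start += region.length
    return out


def motif_seed_alignment(bundle: TruthBundle, motif: str,
                         rows_per_group: int = 2) -> MultipleAlignment:
    """Seed alignment for one motif region: the true-alignment columns of the
    region, a few members per tier (emulating the small initial species set
    used to train the screening fingerprints)."""
    lo, hi = bundle.motif_regions[motif]
    chosen: list[str] = []
    for tier in bundle.config.group_names:
        members = sorted(m for m, g in bundle.groups.items() if g == tier)
        chosen.extend(members[:rows_per_group])
    records = [
        (rid, bundle.alignment.row(rid)[lo - 1 : hi]) for rid in chosen
    ]
    return MultipleAlignment(records=records)


# ---------------------------------------------------------------------------
# bundle output

def write_benchmark(bundle: TruthBundle, outdir: str | Path) -> Path:
    """Write the bundle atomically (build in a staging dir, then rename)."""
    outdir = Path(outdir)
    staging = outdir.with_name(outdir.name + ".partial")
    if staging.exists():
        import shutil

        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        write_fasta(bundle.sequences + bundle.decoys, staging / "sequences.fasta")
        write_alignment_fasta(bundle.alignment, staging / "true_alignment.fasta")
        (staging / "species_tree.nwk").write_text(write_newick(bundle.species_tree))
        (staging / "gene_tree.nwk").write_text(write_newick(bundle.gene_tree))
        write_species_map(bundle.species_map, staging / "species_map.tsv")
        with open(staging / "groups.tsv", "w") as fh:
            fh.write("seq_id\tgroup\n")
            for sid in sorted(bundle.groups):
                fh.write(f"{sid}\t{bundle.groups[sid]}\n")
        with open(staging / "tm_truth.tsv", "w") as fh:
            fh.write("start_col\tend_col\n")
            for lo, hi in bundle.tm_intervals:
                fh.write(f"{lo}\t{hi}\n")
        with open(staging / "sites_truth.tsv", "w") as fh:
            fh.write("group\tcolumn\n")
            for g, c in bundle.planted_site_columns:
                fh.write(f"{g}\t{c}\n")
        with open(staging / "motif_regions.tsv", "w") as fh:
            fh.write("motif\tstart_col\tend_col\n")
            for name, (lo, hi) in sorted(bundle.motif_regions.items()):
                fh.write(f"{name}\t{lo}\t{hi}\n")
        (staging / "manifest.json").write_text(
            json.dumps(bundle.manifest, sort_keys=True, indent=2) + "\n"
        )
    except BaseException:
        import shutil

        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        import shutil

        shutil.rmtree(outdir)
    staging.rename(outdir)
    return outdir
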