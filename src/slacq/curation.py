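"""Semi-automatic curation of screened candidates.

Screened candidate sets contain false positives. Curation scores all
n(n-1)/2 candidate pairs by global percent identity, removes near-duplicate
pairs (identity above a high cut-off, default 97) and unrelated pairs
(below a low cut-off, default 20), lets the surviving pairs fragment the
candidates into connected groups, and selects the group most similar to a
set of reference channels (the five A. thaliana SLAC/SLAH proteins in the
original analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import ProteinSequence, RegionSpec, extract_region


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    """Global pairwise-alignment scoring: BLOSUM62, affine gaps 10/0.5."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _make_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load(config.matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _sanitize(residues: str, alphabet: str) -> str:
    # substitution matrices lack 'X'; map it to the matrix wildcard if present
    if "X" in residues and "X" not in alphabet:
        wildcard = "*" if "*" in alphabet else alphabet[0]
        return residues.replace("X", wildcard)
    return residues


def global_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    scoring_config: ScoringConfig | None = None,
) -> float:
    """Percent identity over a Needleman–Wunsch global alignment.

    Identity = 100 * (identical aligned residue pairs) / (alignment columns);
    a column gapped in one sequence counts in the denominator. 'X' never
    counts as identical.
    """
    config = scoring_config or ScoringConfig()
    aligner = _make_aligner(config)
    alphabet = "".join(aligner.substitution_matrix.alphabet)
    ra = _sanitize(a.residues, alphabet)
    rb = _sanitize(b.residues, alphabet)
    aln = aligner.align(ra, rb)[0]
    ta, tb = aln[0], aln[1]
    ncol = len(ta)
    matches = sum(
        1 for x, y in zip(ta, tb) if x == y and x not in ("-", "*", "X")
    )
    return 100.0 * matches / ncol


@dataclass
class PairScore:
    id_a: str
    id_b: str
    percent_identity: float


@dataclass
class SimilarityGraph:
    vertices: list[str]
    edges: list[PairScore]
    removed_as_duplicate: list[str]


@dataclass
class CandidateGroup:
    members: list[str]
    ref_identity: dict[str, float] = field(default_factory=dict)  # ref id -> best member identity
    reference_score: float = 0.0  # mean over refs of best member identity


def curate(
    candidates: list[ProteinSequence],
    refs: list[ProteinSequence],
    low: float = 20.0,
    high: float = 97.0,
    scoring_config: ScoringConfig | None = None,
) -> tuple[CandidateGroup, SimilarityGraph, list[CandidateGroup]]:
    """Pairwise-identity curation and reference-anchored group selection.

    All n(n-1)/2 candidate pairs are scored. Pairs above ``high`` collapse
    the later-seen member into the earlier one (first-by-input-order
    representative, deterministic); pairs below ``low`` contribute no edge;
    the remaining edges fragment the survivors into connected groups
    (isolated candidates form singleton groups). The selected group maximizes
    the mean over references of the best member identity to that reference.
    """
    if not candidates:
        raise CurationError("no candidates to curate")
    if not refs:
        raise CurationError("no reference sequences given")
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise CurationError("duplicate candidate ids")

    by_id = {c.id: c for c in candidates}
    pair_scores: dict[tuple[str, str], float] = {}
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            pid = global_identity(candidates[i], candidates[j], scoring_config)
            pair_scores[(ids[i], ids[j])] = pid

    # duplicate collapse: iterate pairs in input order, keep first-seen member
    removed: list[str] = []
    removed_set: set[str] = set()
    for (ia, ib), pid in pair_scores.items():
        if pid > high and ia not in removed_set and ib not in removed_set:
            removed.append(ib)
            removed_set.add(ib)
    survivors = [i for i in ids if i not in removed_set]
    if not survivors:
        raise CurationError("all candidates collapsed as duplicates")

    graph = nx.Graph()
    graph.add_nodes_from(survivors)
    edges: list[PairScore] = []
    for (ia, ib), pid in pair_scores.items():
        if ia in removed_set or ib in removed_set:
            continue
        if low <= pid <= high:
            graph.add_edge(ia, ib)
            edges.append(PairScore(ia, ib, pid))

    groups: list[CandidateGroup] = []
    components = [sorted(c, key=survivors.index) for c in nx.connected_components(graph)]
    components.sort(key=lambda comp: survivors.index(comp[0]))
    for comp in components:
        ref_identity = {
            r.id: max(global_identity(by_id[m], r, scoring_config) for m in comp)
            for r in refs
        }
        score = sum(ref_identity.values()) / len(refs)
        groups.append(CandidateGroup(members=comp, ref_identity=ref_identity,
                                     reference_score=score))
    selected = max(groups, key=lambda g: g.reference_score)
    sim_graph = SimilarityGraph(vertices=survivors, edges=edges,
                                removed_as_duplicate=removed)
    return selected, sim_graph, groups


@dataclass
class CompletenessReport:
    complete: bool
    best_reference: str
    missing_fraction: float
    region_coverage: dict[str, float]  # region label -> covered fraction


def completeness_check(
    candidate: ProteinSequence,
    reference_set: list[ProteinSequence],
    region_specs: dict[str, list[RegionSpec]] | None = None,
    max_missing_frac: float = 0.1,
    scoring_config: ScoringConfig | None = None,
) -> CompletenessReport:
    """Coverage-based completeness against the best-matching reference.

    The candidate is globally aligned to the reference it matches best; the
    reference region (by default the full reference) is *covered* at a
    position when the alignment places a candidate residue there. A candidate
    is incomplete when more than ``max_missing_frac`` of the region is
    uncovered — the signature of internal deletions or truncations from
    mispredicted splice sites. Extra candidate sequence (e.g. an N-terminal
    extension) never counts against completeness.

    ``region_specs`` maps reference id to the regions to check on that
    reference; references without an entry are checked over their full
    length.
    """
    if not reference_set:
        raise CurationError("empty reference set")
    config = scoring_config or ScoringConfig()
    best_ref = max(reference_set,
                   key=lambda r: global_identity(candidate, r, config))

    aligner = _make_aligner(config)
    alphabet = "".join(aligner.substitution_matrix.alphabet)
    aln = aligner.align(_sanitize(candidate.residues, alphabet),
                        _sanitize(best_ref.residues, alphabet))[0]
    cand_row, ref_row = aln[0], aln[1]

    # per-reference-position coverage flags
    covered: list[bool] = []
    for x, y in zip(cand_row, ref_row):
        if y != "-":
            covered.append(x != "-")

    regions = None if region_specs is None else region_specs.get(best_ref.id)
    if regions:
        coverage: dict[str, float] = {}
        worst_missing = 0.0
        for spec in regions:
            extract_region(best_ref, spec)  # validates coordinates/anchors
            window = covered[spec.start_pos - 1 : spec.end_pos]
            frac = sum(window) / len(window)
            coverage[f"{spec.start_pos}_{spec.end_pos}"] = frac
            worst_missing = max(worst_missing, 1.0 - frac)
    else:
        frac = sum(covered) / len(covered)
        coverage = {f"1_{len(best_ref)}": frac}
        worst_missing = 1.0 - frac

    return CompletenessReport(
        complete=worst_missing <= max_missing_frac,
        best_reference=best_ref.id,
        missing_fraction=worst_missing,
        region_coverage=coverage,
    )


def write_pair_table(pairs: list[PairScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.percent_identity:.2f}\n")


def write_group_report(groups: list[CandidateGroup], selected: CandidateGroup,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tmember_id\tselected_flag\n")
        for gi, g in enumerate(groups, 1):
            flag = int(g is selected)
            for m in g.members:
                fh.write(f"g{gi}\t{m}\t{flag}\n")
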