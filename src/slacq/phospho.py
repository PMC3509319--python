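"""Phosphosite scoring and the group-conserved site screen.

Kinase-target prediction itself is delegated to a pluggable scorer contract:
any object with ``score(seq) -> array`` producing values in [0, 1] at
Ser/Thr/Tyr positions (NaN elsewhere). Two implementations ship:

* :class:`TableScorer` — adapter for precomputed per-residue score tables
  (TSV) produced by an external predictor;
* :class:`SurrogatePWMScorer` — a transparent position-weight-matrix scorer
  (basophilic kinase-like context weights over a ±4 window, squashed through
  a logistic), used by the synthetic benchmarks.

The screen itself looks for alignment columns where, within one ortholog
group, (i) more than 90% of the members carry the phospho-acceptor class
(Ser/Thr interchangeable; Tyr separate), (ii) at least one member scores
above 0.6, and (iii) the group-average score exceeds 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .sequences import GAP, AMINO_ACIDS, MultipleAlignment, ProteinSequence
from .tracks import ColumnTrack, ResidueTrack, project_tracks

ACCEPTORS = frozenset("STY")
ST_CLASS = frozenset("ST")
Y_CLASS = frozenset("Y")


class PhosphoError(ValueError):
    pass


class PhosphoScorer(Protocol):
    def score(self, seq: ProteinSequence) -> np.ndarray:
        """Per-residue scores in [0, 1]; NaN at non-S/T/Y positions."""
        ...


#: Shipped surrogate context weights: {offset relative to the acceptor:
#: {residue: weight}}. Tuned to a basophilic consensus (Arg/Lys upstream,
#: small residues downstream); the logistic bias keeps unrelated contexts
#: near zero so that only near-consensus contexts clear the 0.6 criterion.
SURROGATE_WEIGHTS: dict[int, dict[str, float]] = {
    -4: {"K": 1.0, "R": 1.0},
    -3: {"R": 4.0, "K": 3.0},
    -2: {"R": 3.0, "K": 2.5},
    -1: {"Q": 1.0, "S": 0.5},
    1: {"G": 2.0, "S": 1.0, "A": 0.5},
    2: {"P": 2.0, "L": 1.0},
    3: {"E": 0.5},
    4: {"E": 0.5},
}
SURROGATE_BIAS = -7.0
#: context that maximizes the surrogate score (acceptor at center)
SURROGATE_CONSENSUS_CONTEXT = "KRRQ.GPEE"


@dataclass
class SurrogatePWMScorer:
    """Logistic transform of a ±4-window position-weight score."""

    weights: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SURROGATE_WEIGHTS.items()}
    )
    bias: float = SURROGATE_BIAS

    def raw_score(self, seq: ProteinSequence, pos0: int) -> float:
        total = self.bias
        for off, table in self.weights.items():
            i = pos0 + off
            if 0 <= i < len(seq.residues):
                total += table.get(seq.residues[i], 0.0)
        return total

    def score(self, seq: ProteinSequence) -> np.ndarray:
        out = np.full(len(seq.residues), np.nan)
        for i, ch in enumerate(seq.residues):
            if ch in ACCEPTORS:
                out[i] = 1.0 / (1.0 + math.exp(-self.raw_score(seq, i)))
        return out


@dataclass
class TableScorer:
    """Adapter for precomputed per-residue score tables.

    Table format: TSV with columns seq_id, position (1-based), residue,
    score. Scores outside [0, 1] are rejected; listed positions must carry
    S/T/Y.
    """

    scores: dict[tuple[str, int], float]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableScorer":
        table: dict[tuple[str, int], float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0] == "seq_id":
                    continue
                sid, pos, _residue, score = parts[:4]
                table[(sid, int(pos))] = float(score)
        return cls(scores=table)

    def score(self, seq: ProteinSequence) -> np.ndarray:
        out = np.full(len(seq.residues), np.nan)
        for i, ch in enumerate(seq.residues):
            if ch in ACCEPTORS:
                val = self.scores.get((seq.id, i + 1))
                if val is not None:
                    out[i] = val
        return out


def phospho_scores(seq: ProteinSequence, scorer: PhosphoScorer) -> ResidueTrack:
    """Score one sequence through the contract, validating the [0, 1] range."""
    vals = np.asarray(scorer.score(seq), float)
    if vals.shape != (len(seq.residues),):
        raise PhosphoError(
            f"scorer returned {vals.shape} values for {seq.id!r} "
            f"(expected {len(seq.residues)})"
        )
    for i, ch in enumerate(seq.residues):
        if ch not in ACCEPTORS and not math.isnan(vals[i]):
            raise PhosphoError(
                f"{seq.id!r}: score at non-acceptor position {i + 1} ({ch})"
            )
        if not math.isnan(vals[i]) and not (0.0 <= vals[i] <= 1.0):
            raise PhosphoError(
                f"{seq.id!r}: score {vals[i]} at position {i + 1} outside [0, 1]"
            )
    return ResidueTrack(seq_id=seq.id, feature="phospho", scores=vals)


# ---------------------------------------------------------------------------
# the three-criterion screen

@dataclass(frozen=True)
class SiteReport:
    column: int  # 1-based alignment column
    group: str
    residue_class: str  # "ST" | "Y"
    conservation: float
    mean_score: float
    sd_score: float  # population SD
    max_score: float
    representatives: tuple[tuple[str, int, str], ...]  # (seq_id, 1-based pos, residue)


def conserved_site_screen(
    aln: MultipleAlignment,
    groups: dict[str, str],
    tracks: ColumnTrack,
    cons_min: float = 0.90,
    max_min: float = 0.6,
    mean_min: float = 0.2,
    mean_over: str = "carriers",
) -> list[SiteReport]:
    """Columns passing all three group-conservation criteria.

    Per column and group: the acceptor-class conservation counts members
    whose residue at the column belongs to the class (S and T are
    interchangeable; Y is its own class), over all group members. A site is
    reported iff conservation > cons_min AND max carrier score > max_min AND
    the average score > mean_min. With ``mean_over='carriers'`` (default) the
    average runs over members carrying the class; ``'all'`` divides by the
    full group size, counting non-carriers as zero.
    """
    if mean_over not in ("carriers", "all"):
        raise PhosphoError("mean_over must be 'carriers' or 'all'")
    members_by_group: dict[str, list[str]] = {}
    for sid, g in groups.items():
        if sid in tracks.values:
            members_by_group.setdefault(g, []).append(sid)
    rows = {sid: aln.row(sid) for sid in groups if sid in tracks.values}
    # 1-based residue position per (row, column)
    res_pos: dict[str, np.ndarray] = {}
    for sid, row in rows.items():
        pos = np.zeros(aln.ncol, int)
        p = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                p += 1
                pos[c] = p
        res_pos[sid] = pos

    reports: list[SiteReport] = []
    for gname in sorted(members_by_group):
        members = members_by_group[gname]
        n = len(members)
        for c in range(aln.ncol):
            for cls_name, cls in (("ST", ST_CLASS), ("Y", Y_CLASS)):
                carriers = [m for m in members if rows[m][c] in cls]
                conservation = len(carriers) / n
                if conservation <= cons_min:
                    continue
                scores = np.array([tracks.values[m][c] for m in carriers])
                scores = scores[~np.isnan(scores)]
                if scores.size == 0:
                    continue
                max_score = float(scores.max())
                if mean_over == "carriers":
                    mean_score = float(scores.mean())
                    sd_score = float(scores.std())
                else:
                    padded = np.concatenate([scores, np.zeros(n - len(scores))])
                    mean_score = float(padded.mean())
                    sd_score = float(padded.std())
                if max_score > max_min and mean_score > mean_min:
                    reps = tuple(
                        (m, int(res_pos[m][c]), rows[m][c])
                        for m in carriers[:3]
                    )
                    reports.append(SiteReport(
                        column=c + 1, group=gname, residue_class=cls_name,
                        conservation=conservation, mean_score=mean_score,
                        sd_score=sd_score, max_score=max_score,
                        representatives=reps,
                    ))
    return reports


def screen_phosphosites(
    aln: MultipleAlignment,
    groups: dict[str, str],
    scorer: PhosphoScorer,
    **kwargs,
) -> tuple[list[SiteReport], ColumnTrack]:
    """Convenience wrapper: score every grouped sequence, project, screen."""
    tracks = [
        phospho_scores(aln.ungapped(sid), scorer)
        for sid in aln.ids
        if sid in groups
    ]
    col_tracks = project_tracks(tracks, aln)
    return conserved_site_screen(aln, groups, col_tracks, **kwargs), col_tracks


# ---------------------------------------------------------------------------
# position-frequency-matrix export (logo data)

PFM_ALPHABET = AMINO_ACIDS + GAP  # 21 rows


@dataclass
class PositionFrequencyMatrix:
    group: str
    columns: list[int]  # 1-based alignment columns of the window
    freqs: np.ndarray  # (21, width), each column sums to 1


def pfm_window(
    aln: MultipleAlignment,
    column: int,
    halfwidth: int,
    group_members: list[str],
    group: str = "",
) -> PositionFrequencyMatrix:
    """Residue+gap frequencies over group members around a 1-based column."""
    lo = column - halfwidth
    hi = column + halfwidth
    if lo < 1 or hi > aln.ncol:
        raise PhosphoError(
            f"window {lo}..{hi} outside alignment columns 1..{aln.ncol}"
        )
    if not group_members:
        raise PhosphoError("empty group for PFM")
    width = hi - lo + 1
    freqs = np.zeros((len(PFM_ALPHABET), width))
    index = {ch: i for i, ch in enumerate(PFM_ALPHABET)}
    for m in group_members:
        row = aln.row(m)
        for w, c in enumerate(range(lo - 1, hi)):
            ch = row[c]
            freqs[index.get(ch, index[GAP]), w] += 1
    freqs /= len(group_members)
    return PositionFrequencyMatrix(
        group=group, columns=list(range(lo, hi + 1)), freqs=freqs
    )


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(str(c) for c in pfm.columns) + "\n")
        for i, ch in enumerate(PFM_ALPHABET):
            fh.write(ch + "\t" + "\t".join(f"{x:.4f}" for x in pfm.freqs[i]) + "\n")


def write_site_reports(reports: list[SiteReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "column\tgroup\tresidue_class\tconservation\tmean_score\tsd_score"
            "\tmax_score\trepresentatives\n"
        )
        for r in reports:
            reps = ";".join(f"{sid}:{res}{pos}" for sid, pos, res in r.representatives)
            fh.write(
                f"{r.column}\t{r.group}\t{r.residue_class}\t{r.conservation:.3f}"
                f"\t{r.mean_score:.3f}\t{r.sd_score:.3f}\t{r.max_score:.3f}\t{reps}\n"
            )
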