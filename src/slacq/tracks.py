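"""Per-residue feature tracks, alignment projection, clade averaging, and
transmembrane-segment calling.

Workflow: a feature is scored per residue on each ungapped sequence
(Kyte–Doolittle hydropathicity in a sliding window, or phosphosite scores),
projected onto the columns of a master alignment, and averaged per clade —
skipping columns where the gap fraction reaches the mask limit (default
25%). Sustained positive stretches of the clade-averaged hydropathicity
profile are called as candidate transmembrane segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequences import GAP, MultipleAlignment, ProteinSequence

#: Kyte–Doolittle hydropathicity scale (kcal-free arbitrary units).
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
#: 'X' scores as background: the unweighted mean of the 20 scale values.
KD_X = sum(KD_SCALE.values()) / len(KD_SCALE)


class TrackError(ValueError):
    pass


@dataclass
class ResidueTrack:
    """One value (or NaN where undefined) per residue of an ungapped sequence."""

    seq_id: str
    feature: str
    scores: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)


@dataclass
class ColumnTrack:
    """Per-(sequence, column) values on an alignment; NaN where the row is gapped."""

    feature: str
    aln: MultipleAlignment
    values: dict[str, np.ndarray]  # seq_id -> (ncol,) float with NaN


@dataclass
class CladeProfile:
    group: str
    feature: str
    mean: np.ndarray  # (ncol,), NaN where masked
    masked: np.ndarray  # (ncol,) bool
    mask_reason: list[str | None]  # per column


@dataclass(frozen=True)
class TMSegment:
    start_col: int  # 1-based inclusive alignment columns
    end_col: int
    mean_hydropathicity: float
    clade: str


def kd_hydropathicity(seq: ProteinSequence, window: int = 19) -> ResidueTrack:
    """Sliding-window mean of Kyte–Doolittle values, centered, full windows only.

    Positions whose centered window would run off either end are missing.
    ``window`` must be odd; a window longer than the sequence yields an
    all-missing track.
    """
    if window < 1 or window % 2 == 0:
        raise TrackError("window must be odd and >= 1")
    vals = np.array([KD_SCALE.get(ch, KD_X) for ch in seq.residues])
    n = len(vals)
    scores = np.full(n, np.nan)
    half = window // 2
    if window <= n:
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for i in range(half, n - half):
            scores[i] = (csum[i + half + 1] - csum[i - half]) / window
    return ResidueTrack(seq_id=seq.id, feature=f"kd_w{window}", scores=scores)


def project(track: ResidueTrack, aln: MultipleAlignment) -> np.ndarray:
    """Place per-residue values at the alignment columns carrying each residue.

    Returns an (ncol,) array with NaN at gap columns. The defined values are
    a bijective, order-preserving image of the track's defined values.
    """
    row = aln.row(track.seq_id)
    cols = aln.residue_to_column(track.seq_id)
    if len(cols) != len(track.scores):
        raise TrackError(
            f"track for {track.seq_id!r} has {len(track.scores)} residues but "
            f"alignment row ungaps to {len(cols)}"
        )
    out = np.full(aln.ncol, np.nan)
    out[cols] = track.scores
    return out


def project_tracks(tracks: list[ResidueTrack], aln: MultipleAlignment) -> ColumnTrack:
    if not tracks:
        raise TrackError("no tracks to project")
    feature = tracks[0].feature
    values = {t.seq_id: project(t, aln) for t in tracks}
    return ColumnTrack(feature=feature, aln=aln, values=values)


def clade_average(
    tracks: ColumnTrack,
    groups: dict[str, str],
    max_gap_frac: float = 0.25,
) -> dict[str, CladeProfile]:
    """Per-clade (and overall, key ``"all"``) column means with the gap mask.

    A column is masked for an averaging set when the fraction of its
    sequences gapped there is >= ``max_gap_frac`` (i.e. averages are computed
    only where *less than* 25% of the sequences show gaps, at the default).
    Missing feature values on residue-bearing positions (e.g. window
    truncation) are skipped in the mean but do not count as gaps.
    """
    aln = tracks.aln
    member_sets: dict[str, list[str]] = {"all": list(tracks.values)}
    for g in groups.values():
        member_sets.setdefault(g, [])
    for sid, g in groups.items():
        if sid in tracks.values:
            member_sets[g].append(sid)
    profiles: dict[str, CladeProfile] = {}
    for gname, members in member_sets.items():
        if not members:
            raise TrackError(f"empty group {gname!r}: no member has a track")
        rows = np.stack([tracks.values[m] for m in members])
        gapped = np.stack([
            np.array([ch == GAP for ch in aln.row(m)]) for m in members
        ])
        gap_frac = gapped.mean(axis=0)
        masked = gap_frac >= max_gap_frac
        data = np.where(gapped, np.nan, rows)
        n_def = (~np.isnan(data)).sum(axis=0)
        col_mean = np.where(
            n_def > 0, np.nansum(data, axis=0) / np.maximum(n_def, 1), np.nan
        )
        col_mean[masked] = np.nan
        reasons: list[str | None] = [
            f"gap_fraction {gap_frac[c]:.2f} >= {max_gap_frac}" if masked[c] else None
            for c in range(aln.ncol)
        ]
        profiles[gname] = CladeProfile(
            group=gname, feature=tracks.feature,
            mean=col_mean, masked=masked, mask_reason=reasons,
        )
    return profiles


def call_tm_segments(
    profile: CladeProfile,
    score_min: float = 1.0,
    min_len: int = 10,
) -> list[TMSegment]:
    """Maximal runs of unmasked columns with mean >= score_min, length >= min_len.

    Masked columns and NaN means break runs.
    """
    good = np.zeros(len(profile.mean), bool)
    for c, v in enumerate(profile.mean):
        good[c] = (not profile.masked[c]) and not math.isnan(v) and v >= score_min
    segments: list[TMSegment] = []
    start = None
    for c in range(len(good) + 1):
        flag = good[c] if c < len(good) else False
        if flag and start is None:
            start = c
        elif not flag and start is not None:
            if c - start >= min_len:
                segments.append(TMSegment(
                    start_col=start + 1, end_col=c,
                    mean_hydropathicity=float(np.nanmean(profile.mean[start:c])),
                    clade=profile.group,
                ))
            start = None
    return segments


def segment_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two 1-based inclusive column intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def write_profile_tsv(profiles: dict[str, CladeProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tgroup\tmean\tmask\treason\n")
        for gname, p in profiles.items():
            for c in range(len(p.mean)):
                mean = "" if math.isnan(p.mean[c]) else f"{p.mean[c]:.4f}"
                fh.write(
                    f"{c + 1}\t{gname}\t{mean}\t{int(bool(p.masked[c]))}"
                    f"\t{p.mask_reason[c] or ''}\n"
                )
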