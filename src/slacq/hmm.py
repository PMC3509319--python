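"""Profile HMMs for motif screening.

A profile HMM is built from a gapped seed alignment of one motif region
(e.g. one of the pore-lining transmembrane segments used to fingerprint
SLAC-like channels). Scoring is *glocal*: the full model must be traversed
(through match or delete states) but the target's flanking residues are free,
which is the right mode for finding short internal membrane-segment motifs in
whole protein sequences. Scores are log2-odds (bits) against an i.i.d.
background; statistical significance comes from a Gumbel calibration on
simulated background sequences, and a proteome screen keeps a protein when at
least one motif matches with E-value at or below the cut-off.

The architecture is deliberately smaller than HMMER's Plan7: single-hit
glocal mode only, no biased-composition corrections, no multi-hit wing
retraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gumbel_r

from .sequences import AMINO_ACIDS, GAP, MultipleAlignment, ProteinSequence

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)

LOG2 = math.log(2.0)
NEG_INF = -np.inf


class HMMError(ValueError):
    pass


@dataclass
class GumbelCalibration:
    """Location/scale of the null score distribution: P(S >= s) = 1 - exp(-exp(-lam*(s-mu)))."""

    mu: float
    lam: float
    n_random: int
    len_random: int
    seed: int

    def pvalue(self, score: float) -> float:
        return float(gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lam))

    def evalue(self, score: float, n_db: int) -> float:
        return n_db * self.pvalue(score)


@dataclass
class ProfileHMM:
    """Position-specific motif model with match/insert/delete states.

    Transition arrays are indexed by *node*: index ``j`` holds transitions
    leaving node ``j`` toward node ``j+1`` (node 0 is the begin state, node K
    the last match). Inserts exist between consecutive match states only; the
    target's flanks are handled by the free-flank scoring mode rather than by
    terminal insert states.
    """

    motif_id: str
    match_emissions: np.ndarray  # (K, 20), rows sum to 1
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray  # (K+1,)  M_j -> M_{j+1} (j=0: begin->M1; j=K: M_K->end)
    t_mi: np.ndarray  # (K+1,)  M_j -> I_j    (0 at j=0 and j=K)
    t_md: np.ndarray  # (K+1,)  M_j -> D_{j+1} (0 at j=K)
    t_im: np.ndarray  # (K+1,)  I_j -> M_{j+1}
    t_ii: np.ndarray  # (K+1,)  I_j -> I_j
    t_dm: np.ndarray  # (K+1,)  D_j -> M_{j+1} (j=K: D_K->end)
    t_dd: np.ndarray  # (K+1,)  D_j -> D_{j+1}
    pseudocount_weight: float = 1.0
    calibration: GumbelCalibration | None = None

    @property
    def K(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        if self.K < 2:
            raise HMMError(f"model {self.motif_id!r}: need K >= 2 match states")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise HMMError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise HMMError("insert emissions must sum to 1")
        for arrs, name in (
            ((self.t_mm, self.t_mi, self.t_md), "M"),
            ((self.t_im, self.t_ii), "I"),
            ((self.t_dm, self.t_dd), "D"),
        ):
            total = sum(arrs)
            # distributions are normalized where the source state exists
            mask = total > 0
            if not np.allclose(total[mask], 1.0, atol=1e-9):
                raise HMMError(f"{name}-state transitions must sum to 1")

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif_id: str
    bit_score: float
    evalue: float
    start: int  # 1-based span on the target; (0, 0) for emission-free paths
    end: int


@dataclass
class ScreenResult:
    kept: list[str]
    evalue_max: float
    best_hits: dict[str, dict[str, MotifHit]]  # seq_id -> motif_id -> hit
    presence: dict[str, dict[str, bool]]  # seq_id -> motif_id -> passes threshold


# ---------------------------------------------------------------------------
# model construction

def build_profile(
    seed: MultipleAlignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    motif_id: str = "motif",
) -> ProfileHMM:
    """Build a profile HMM from a gapped seed alignment.

    Columns with gap fraction < 0.5 become match states. Match emissions use
    background-proportional pseudocounts:
    ``(count + w * background) / (n_eff + w)`` with ``n_eff`` the number of
    residues observed in the column ('X' is excluded from counts). Transition
    probabilities are estimated from the state paths implied by the seed rows,
    with one pseudocount per legal transition. Deterministic given the seed.
    """
    if seed.nrow < 2:
        raise HMMError("seed alignment needs at least 2 rows")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    w = float(pseudocount_weight)

    ncol = seed.ncol
    nrow = seed.nrow
    gap_frac = np.array(
        [seed.column(c).count(GAP) / nrow for c in range(ncol)]
    )
    is_match = gap_frac < 0.5
    K = int(is_match.sum())
    if K == 0:
        raise HMMError("seed has zero match columns (all columns >= 50% gaps)")

    # emissions
    match_cols = np.flatnonzero(is_match)
    emissions = np.zeros((K, 20))
    for k, c in enumerate(match_cols):
        counts = np.zeros(20)
        for ch in seed.column(c):
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
        n_eff = counts.sum()
        emissions[k] = (counts + w * bg) / (n_eff + w)

    # transitions from implied state paths; one pseudocount per legal move
    c_mm = np.ones(K + 1)
    c_mi = np.ones(K + 1)
    c_md = np.ones(K + 1)
    c_im = np.ones(K + 1)
    c_ii = np.ones(K + 1)
    c_dm = np.ones(K + 1)
    c_dd = np.ones(K + 1)
    # inserts do not exist at the ends; deletes cannot leave the end node
    c_mi[0] = c_mi[K] = 0.0
    c_md[K] = 0.0
    c_im[0] = c_ii[0] = c_im[K] = c_ii[K] = 0.0
    c_dm[0] = c_dd[0] = 0.0
    c_dd[K] = 0.0

    col_state = np.where(is_match, "M", "I")
    for _, row in seed.records:
        node = 0  # current model node; state of the walker at that node
        state = "M"  # begin behaves like a match node
        for c in range(ncol):
            ch = row[c]
            if col_state[c] == "M":
                new_state = "M" if ch != GAP else "D"
                key = state + new_state
                if key == "MM":
                    c_mm[node] += 1
                elif key == "MD":
                    c_md[node] += 1
                elif key == "IM":
                    c_im[node] += 1
                elif key == "ID":
                    # I->D is not part of the reduced architecture; route I->M->D
                    c_im[node] += 1
                    c_md[node + 1] += 0  # no extra mass; approximation noted
                elif key == "DM":
                    c_dm[node] += 1
                elif key == "DD":
                    c_dd[node] += 1
                node += 1
                state = new_state
            else:
                if ch != GAP:
                    if state == "M":
                        c_mi[node] += 1
                    elif state == "I":
                        c_ii[node] += 1
                    # D->I is likewise routed through match; ignore
                    state = "I"
        # exit to end
        if state == "M":
            c_mm[node] += 1
        elif state == "D":
            c_dm[node] += 1
        else:
            c_im[node] += 1

    def _norm(*arrs: np.ndarray) -> None:
        total = sum(arrs)
        for a in arrs:
            np.divide(a, total, out=a, where=total > 0)

    _norm(c_mm, c_mi, c_md)
    _norm(c_im, c_ii)
    _norm(c_dm, c_dd)

    model = ProfileHMM(
        motif_id=motif_id,
        match_emissions=emissions,
        insert_emissions=bg.copy(),
        background=bg.copy(),
        t_mm=c_mm, t_mi=c_mi, t_md=c_md,
        t_im=c_im, t_ii=c_ii,
        t_dm=c_dm, t_dd=c_dd,
        pseudocount_weight=w,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# scoring

def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), NEG_INF)


def _emission_logodds(model: ProfileHMM, seq: ProteinSequence) -> np.ndarray:
    """(K, L) match-emission log2-odds; 'X' scores 0 (background)."""
    K, L = model.K, len(seq)
    lem = np.zeros((K, L))
    lodds = _log2(model.match_emissions) - _log2(model.background)[None, :]
    for i, ch in enumerate(seq.residues):
        if ch in AA_INDEX:
            lem[:, i] = lodds[:, AA_INDEX[ch]]
        # X: 0 everywhere
    return lem


def _transition_logs(model: ProfileHMM) -> dict[str, np.ndarray]:
    return {
        name: _log2(getattr(model, name))
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
    }


def viterbi_local(model: ProfileHMM, seq: ProteinSequence) -> tuple[float, int, int]:
    """Best glocal match: full model, free target flanks.

    Returns ``(bit_score, start, end)`` with a 1-based inclusive span on the
    target; a best path with no match emissions (all-delete traversal)
    reports span ``(0, 0)``.
    """
    K, L = model.K, len(seq)
    lem = _emission_logodds(model, seq)
    lt = _transition_logs(model)
    t_mm, t_mi, t_md = lt["t_mm"], lt["t_mi"], lt["t_md"]
    t_im, t_ii = lt["t_im"], lt["t_ii"]
    t_dm, t_dd = lt["t_dm"], lt["t_dd"]

    # state (j, i): j = model node 1..K, i = residues consumed 0..L
    VM = np.full((K + 1, L + 1), NEG_INF)
    VI = np.full((K + 1, L + 1), NEG_INF)
    VD = np.full((K + 1, L + 1), NEG_INF)
    SM = np.zeros((K + 1, L + 1), int)  # first emitted residue of the path
    SI = np.zeros((K + 1, L + 1), int)
    SD = np.zeros((K + 1, L + 1), int)

    # delete chains reachable from begin at any consumption offset (free flank)
    VD[1, :] = t_md[0]
    for j in range(2, K + 1):
        VD[j, :] = VD[j - 1, 0] + t_dd[j - 1]
    chain_ok = bool(np.all(np.isfinite(t_dd[1:K])))

    for i in range(1, L + 1):
        pm, pi, pd = VM[:, i - 1], VI[:, i - 1], VD[:, i - 1]
        # M_j for j >= 2 from (M/I/D)_{j-1} at i-1
        if K >= 2:
            cand = np.stack([
                pm[1:K] + t_mm[1:K],
                pi[1:K] + t_im[1:K],
                pd[1:K] + t_dm[1:K],
            ])
            src = cand.argmax(axis=0)
            best = cand[src, np.arange(K - 1)]
            starts = np.stack([SM[1:K, i - 1], SI[1:K, i - 1], SD[1:K, i - 1]])
            chosen = starts[src, np.arange(K - 1)]
            VM[2:, i] = best + lem[1:, i - 1]
            SM[2:, i] = np.where(chosen == 0, i, chosen)
        # M_1: fresh start just before i
        VM[1, i] = t_mm[0] + lem[0, i - 1]
        SM[1, i] = i
        # I_j for j = 1..K-1 from (M/I)_j at i-1
        if K >= 2:
            ai = pm[1:K] + t_mi[1:K]
            bi = pi[1:K] + t_ii[1:K]
            take_m = ai >= bi
            VI[1:K, i] = np.where(take_m, ai, bi)
            SI[1:K, i] = np.where(take_m, SM[1:K, i - 1], SI[1:K, i - 1])
        # D_j by prefix scan: VD[j] = cs[j-1] + max_{m<j} (S_m - cs[m]) where
        # S_0 is the begin entry, S_m the hop from M_m, and cs the cumulative
        # delete-chain cost; ties prefer the latest M source
        if chain_ok:
            S = np.empty(K)
            S[0] = t_md[0]
            S[1:] = VM[1:K, i] + t_md[1:K]
            cs = np.concatenate([[0.0], np.cumsum(t_dd[1:K])])
            am = S - cs
            run = np.maximum.accumulate(am)
            src = np.maximum.accumulate(np.where(am >= run, np.arange(K), -1))
            VD[1:, i] = cs + run
            SD[1:, i] = np.where(src == 0, 0, SM[src, i])
        else:
            # a zero-probability delete chain: sequential scan stays exact
            for j in range(2, K + 1):
                a = VM[j - 1, i] + t_md[j - 1]
                b = VD[j - 1, i] + t_dd[j - 1]
                if a >= b:
                    VD[j, i] = a
                    SD[j, i] = SM[j - 1, i]
                else:
                    VD[j, i] = b
                    SD[j, i] = SD[j - 1, i]

    # exit: M_K -> end (t_mm[K]) or D_K -> end (t_dm[K])
    best_score = NEG_INF
    best_span = (0, 0)
    for i in range(0, L + 1):
        sm = VM[K, i] + t_mm[K]
        if sm > best_score:
            best_score = sm
            best_span = (int(SM[K, i]), i)
        sd = VD[K, i] + t_dm[K]
        if sd > best_score:
            best_score = sd
            span_start = int(SD[K, i])
            best_span = (span_start, i if span_start else 0)
    return float(best_score), best_span[0], best_span[1]


def forward_local(model: ProfileHMM, seq: ProteinSequence) -> float:
    """Log2 of the summed odds over all glocal paths; always >= the Viterbi score.

    Every (start offset, state path) combination counts as a distinct path,
    mirroring the exhaustive enumeration semantics.
    """
    K, L = model.K, len(seq)
    # natural-log space internally; converted to bits at the end
    lem = _emission_logodds(model, seq) * LOG2
    lt = {k: v * LOG2 for k, v in _transition_logs(model).items()}
    t_mm, t_mi, t_md = lt["t_mm"], lt["t_mi"], lt["t_md"]
    t_im, t_ii = lt["t_im"], lt["t_ii"]
    t_dm, t_dd = lt["t_dm"], lt["t_dd"]

    FM = np.full((K + 1, L + 1), NEG_INF)
    FI = np.full((K + 1, L + 1), NEG_INF)
    FD = np.full((K + 1, L + 1), NEG_INF)
    FD[1, :] = t_md[0]
    for j in range(2, K + 1):
        FD[j, :] = FD[j - 1, 0] + t_dd[j - 1]
    chain_ok = bool(np.all(np.isfinite(t_dd[1:K])))

    with np.errstate(invalid="ignore"):
        for i in range(1, L + 1):
            pm, pi, pd = FM[:, i - 1], FI[:, i - 1], FD[:, i - 1]
            if K >= 2:
                entry = np.logaddexp(
                    np.logaddexp(pm[1:K] + t_mm[1:K], pi[1:K] + t_im[1:K]),
                    pd[1:K] + t_dm[1:K],
                )
                FM[2:, i] = entry + lem[1:, i - 1]
                FI[1:K, i] = np.logaddexp(pm[1:K] + t_mi[1:K], pi[1:K] + t_ii[1:K])
            FM[1, i] = t_mm[0] + lem[0, i - 1]
            # D_j by prefix scan, summed analog of the Viterbi delete chain
            if chain_ok:
                S = np.empty(K)
                S[0] = t_md[0]
                S[1:] = FM[1:K, i] + t_md[1:K]
                cs = np.concatenate([[0.0], np.cumsum(t_dd[1:K])])
                FD[1:, i] = cs + np.logaddexp.accumulate(S - cs)
            else:
                for j in range(2, K + 1):
                    FD[j, i] = np.logaddexp(
                        FM[j - 1, i] + t_md[j - 1], FD[j - 1, i] + t_dd[j - 1]
                    )

    terms = np.concatenate([FM[K, :] + t_mm[K], FD[K, :] + t_dm[K]])
    finite = terms[terms > NEG_INF]
    if finite.size == 0:
        return NEG_INF
    return float(logsumexp(finite) / LOG2)


# ---------------------------------------------------------------------------
# calibration and screening

def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Fit Gumbel (mu, lambda) to a score sample by maximum likelihood."""
    scores = np.asarray(scores, float)
    if scores.std() < 1e-12:
        raise HMMError("degenerate score variance: cannot calibrate")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def random_background_sequence(rng: np.random.Generator, length: int,
                               background: np.ndarray) -> ProteinSequence:
    idx = rng.choice(20, size=length, p=background / background.sum())
    return ProteinSequence(id="bg", residues="".join(AMINO_ACIDS[i] for i in idx))


def calibrate_evalue(
    model: ProfileHMM,
    n_random: int = 1000,
    len_random: int = 400,
    seed: int = 0,
) -> GumbelCalibration:
    """Fit the null Viterbi-score distribution on i.i.d. background sequences."""
    if n_random < 100:
        raise HMMError("n_random must be >= 100 for a usable calibration")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for r in range(n_random):
        seq = random_background_sequence(rng, len_random, model.background)
        scores[r], _, _ = viterbi_local(model, seq)
    mu, lam = fit_gumbel(scores)
    cal = GumbelCalibration(mu=mu, lam=lam, n_random=n_random,
                            len_random=len_random, seed=seed)
    model.calibration = cal
    return cal


def screen_proteome(
    models: list[ProfileHMM],
    proteome: list[ProteinSequence],
    evalue_max: float = 1e-3,
) -> ScreenResult:
    """Keep every protein for which at least one motif matches at E <= evalue_max.

    Kept entries refer to full sequences, never fragments. E-values use the
    proteome size as the database size, so they scale with the search space.
    """
    if not models:
        raise HMMError("need at least one motif model")
    for m in models:
        if m.calibration is None:
            raise HMMError(f"model {m.motif_id!r} is not calibrated")
    n_db = len(proteome)
    kept: list[str] = []
    best_hits: dict[str, dict[str, MotifHit]] = {}
    presence: dict[str, dict[str, bool]] = {}
    for seq in proteome:
        hits: dict[str, MotifHit] = {}
        flags: dict[str, bool] = {}
        for m in models:
            score, start, end = viterbi_local(m, seq)
            ev = m.calibration.evalue(score, n_db)  # type: ignore[union-attr]
            hits[m.motif_id] = MotifHit(
                seq_id=seq.id, motif_id=m.motif_id, bit_score=score,
                evalue=ev, start=start, end=end,
            )
            flags[m.motif_id] = ev <= evalue_max
        best_hits[seq.id] = hits
        presence[seq.id] = flags
        if any(flags.values()):
            kept.append(seq.id)
    return ScreenResult(kept=kept, evalue_max=evalue_max,
                        best_hits=best_hits, presence=presence)


def write_hits_tsv(result: ScreenResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmotif_id\tbit_score\tevalue\tstart\tend\tkept\n")
        for seq_id, hits in result.best_hits.items():
            for motif_id, h in hits.items():
                fh.write(
                    f"{seq_id}\t{motif_id}\t{h.bit_score:.4f}\t{h.evalue:.4g}"
                    f"\t{h.start}\t{h.end}\t{int(seq_id in result.kept)}\n"
                )


# ---------------------------------------------------------------------------
# flat-text model serialization

FORMAT_VERSION = "slacq-hmm/1"


def save_profile(model: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"format\t{FORMAT_VERSION}\n")
        fh.write(f"motif_id\t{model.motif_id}\n")
        fh.write(f"K\t{model.K}\n")
        fh.write(f"pseudocount_weight\t{model.pseudocount_weight}\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")

        def _vec(name: str, v: np.ndarray) -> None:
            fh.write(name + "\t" + "\t".join(format(x, ".12g") for x in v) + "\n")

        _vec("background", model.background)
        _vec("insert_emissions", model.insert_emissions)
        for k in range(model.K):
            _vec(f"match_{k + 1}", model.match_emissions[k])
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            _vec(name, getattr(model, name))
        if model.calibration is not None:
            c = model.calibration
            fh.write(f"calibration\t{c.mu:.12g}\t{c.lam:.12g}\t{c.n_random}"
                     f"\t{c.len_random}\t{c.seed}\n")


def load_profile(path: str | Path) -> ProfileHMM:
    fields: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            fields[parts[0]] = parts[1:]
    if fields.get("format", [""])[0] != FORMAT_VERSION:
        raise HMMError(f"unsupported model format in {path}")
    K = int(fields["K"][0])
    match = np.array([[float(x) for x in fields[f"match_{k + 1}"]] for k in range(K)])
    model = ProfileHMM(
        motif_id=fields["motif_id"][0],
        match_emissions=match,
        insert_emissions=np.array([float(x) for x in fields["insert_emissions"]]),
        background=np.array([float(x) for x in fields["background"]]),
        t_mm=np.array([float(x) for x in fields["t_mm"]]),
        t_mi=np.array([float(x) for x in fields["t_mi"]]),
        t_md=np.array([float(x) for x in fields["t_md"]]),
        t_im=np.array([float(x) for x in fields["t_im"]]),
        t_ii=np.array([float(x) for x in fields["t_ii"]]),
        t_dm=np.array([float(x) for x in fields["t_dm"]]),
        t_dd=np.array([float(x) for x in fields["t_dd"]]),
        pseudocount_weight=float(fields["pseudocount_weight"][0]),
    )
    if "calibration" in fields:
        mu, lam, n_random, len_random, seed = fields["calibration"]
        model.calibration = GumbelCalibration(
            mu=float(mu), lam=float(lam), n_random=int(n_random),
            len_random=int(len_random), seed=int(seed),
        )
    model.validate()
    return model
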