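"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: exhaustive path
enumeration for profile-HMM scoring, a from-scratch affine-gap alignment
enumerator for percent identity, and a min-cost embedding dynamic program
for duplication/loss reconciliation.
"""

from __future__ import annotations

import numpy as np

from slacq import hmm
from slacq.trees import Node, RootedTree


# ---------------------------------------------------------------------------
# profile-HMM: exhaustive enumeration over (start offset, state path)

def enumerate_hmm_scores(model, seq) -> tuple[float, float]:
    """(viterbi, forward) log2-odds by brute-force path enumeration."""
    K, L = model.K, len(seq.residues)
    lt = {
        n: np.where(
            getattr(model, n) > 0,
            np.log2(np.where(getattr(model, n) > 0, getattr(model, n), 1.0)),
            -np.inf,
        )
        for n in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
    }
    lem = hmm._emission_logodds(model, seq)
    best = -np.inf
    total: list[float] = []

    def rec(j: int, s: str, i: int, score: float) -> None:
        nonlocal best
        if j == K and s in ("M", "D"):
            ex = score + (lt["t_mm"][K] if s == "M" else lt["t_dm"][K])
            total.append(ex)
            best = max(best, ex)
        if s == "M":
            nxt = [("M", lt["t_mm"][j]), ("I", lt["t_mi"][j]), ("D", lt["t_md"][j])]
        elif s == "I":
            nxt = [("M", lt["t_im"][j]), ("I", lt["t_ii"][j])]
        else:
            nxt = [("M", lt["t_dm"][j]), ("D", lt["t_dd"][j])]
        for ns, lp in nxt:
            if not np.isfinite(lp):
                continue
            if ns == "M":
                if j + 1 <= K and i < L:
                    rec(j + 1, "M", i + 1, score + lp + lem[j, i])
            elif ns == "I":
                if i < L and 1 <= j <= K - 1:
                    rec(j, "I", i + 1, score + lp)
            else:
                if j + 1 <= K:
                    rec(j + 1, "D", i, score + lp)

    for i0 in range(L + 1):
        if i0 < L:
            rec(1, "M", i0 + 1, lt["t_mm"][0] + lem[0, i0])
        rec(1, "D", i0, lt["t_md"][0])
    fwd = float(np.log2(np.sum(np.exp2(np.array(total))))) if total else -np.inf
    return float(best), fwd


# ---------------------------------------------------------------------------
# pairwise identity: exhaustive alignment enumeration (tiny sequences)

def enumerate_identities(a: str, b: str, score_fn, gap_open: float,
                         gap_extend: float) -> set[float]:
    """Percent identities of every optimal global affine-gap alignment.

    Enumerates all alignments recursively (feasible for |a|,|b| <= 7),
    scoring gap runs with open+extend affine costs, and returns the set of
    identity values among score-optimal alignments.
    """
    results: list[tuple[float, int, int]] = []  # (score, matches, ncol)

    def rec(i: int, j: int, prev: str, score: float, matches: int, ncol: int) -> None:
        if i == len(a) and j == len(b):
            results.append((score, matches, ncol))
            return
        if i < len(a) and j < len(b):
            s = score_fn(a[i], b[j])
            rec(i + 1, j + 1, "M", score + s,
                matches + (1 if a[i] == b[j] else 0), ncol + 1)
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, "A", score - cost, matches, ncol + 1)
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, "B", score - cost, matches, ncol + 1)

    rec(0, 0, "", 0.0, 0, 0)
    best = max(r[0] for r in results)
    return {
        100.0 * m / n for s, m, n in results if abs(s - best) < 1e-9
    }


# ---------------------------------------------------------------------------
# reconciliation: min duplication+loss embedding by DP over species nodes

def min_dl_embedding_cost(gene: RootedTree, species: RootedTree,
                          species_map: dict[str, str]) -> int:
    """Minimal duplications + losses over all embeddings of the gene tree.

    Classic two-table dynamic program: C(g, s) embeds g *at* species node s
    (as a duplication or, at internal s, a speciation); E(g, s) allows g to
    enter the subtree of s, paying one loss per skipped sibling edge. The
    family may originate at any species node (no losses are charged above
    the origin). Independent of the LCA-mapping shortcut used by the package.
    """
    INF = 10**9
    sp_nodes = list(species.postorder())
    gene_nodes = list(gene.postorder())
    sp_leaf = {n.label: n for n in species.leaves()}

    C: dict[tuple[int, int], int] = {}
    E: dict[tuple[int, int], int] = {}

    for s in sp_nodes:
        for g in gene_nodes:
            if g.is_leaf:
                target = sp_leaf[species_map[g.label]]
                c = 0 if target is s else INF
            else:
                g1, g2 = g.children
                options = []
                if s.children:
                    sl, sr = s.children
                    options.append(E[(id(g1), id(sl))] + E[(id(g2), id(sr))])
                    options.append(E[(id(g1), id(sr))] + E[(id(g2), id(sl))])
                # duplication at s: both children present at (or below) s
                options.append(1 + E[(id(g1), id(s))] + E[(id(g2), id(s))])
                c = min(options)
            C[(id(g), id(s))] = c
            e = c
            for child in s.children:
                e = min(e, E[(id(g), id(child))] + 1)
            E[(id(g), id(s))] = e
    return min(C[(id(gene.root), id(s))] for s in sp_nodes)
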