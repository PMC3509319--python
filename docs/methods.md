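# Methods

`slacq` re-implements, as one tested pipeline, the comparative-genomics
workflow used to characterize the two families of plant plasma-membrane
anion channels: the slow (SLAC/SLAH) and quick (QUAC/ALMT) types. The
pipeline has six computational stages — motif-HMM proteome screening,
pairwise-identity curation, UPGMA grouping, gene-tree/species-tree
reconciliation, alignment-projected feature tracks (hydropathicity and
phosphosite scores), and a group-conserved phosphosite screen — plus a
synthetic family generator that provides ground truth for every stage.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Profile-HMM motif screening

A motif model is built from a gapped seed alignment of one fingerprint
region (for SLAC-like channels, the odd-numbered pore-lining transmembrane
segments TM1/3/5/7/9; for ALMT-like channels, two conserved stretches).

* **Match columns.** A seed column becomes a match state when its gap
  fraction is below 0.5 (the usual Plan7-style heuristic). Seeds whose
  columns are all gap-majority are rejected.
* **Emissions.** Match emissions use background-proportional pseudocounts,
  `(count + w·q) / (n_eff + w)` with weight `w = 1` and uniform background
  `q = 1/20` by default ('X' is excluded from counts and scores as
  background). Insert states emit the background.
* **Transitions.** Estimated from the state paths implied by the seed rows
  with one pseudocount per legal transition. The architecture is smaller
  than HMMER's Plan7: single-hit scoring, inserts only between matches, no
  I→D/D→I transitions, no biased-composition filter.
* **Scoring mode.** *Glocal*: the full model must be traversed (matches or
  deletes) but the target's flanks are free. This is the right mode for
  locating short internal membrane-segment motifs in whole proteins, and it
  makes two properties hold exactly: appending flank residues never lowers
  a score, and the seed consensus maximizes the score over equal-length
  targets. Scores are log2-odds (bits); Viterbi and forward recursions are
  exact dynamic programs over (model node, residues consumed), with the
  delete chains evaluated by prefix scans.
* **Significance.** The null Viterbi-score distribution is calibrated by
  simulation: 1000 i.i.d. background sequences of length 400 (both
  config-exposed), maximum-likelihood Gumbel fit via
  `scipy.stats.gumbel_r`. E-value = N·P(S ≥ s) with N the proteome size.
* **Inclusion rule.** A protein is kept when at least one motif hits with
  E ≤ 1e-3, and the *entire* sequence is kept, never the matching fragment.
  The threshold quantity and direction are config-exposed: a raw log-odds
  cut-off of 0.001 would keep nearly everything, so the screening cut-off
  is interpreted as an E-value bound.

## Curation

All n(n−1)/2 candidate pairs are scored by global percent identity
(Needleman–Wunsch via `Bio.Align.PairwiseAligner`; BLOSUM62, gap open 10,
extend 0.5; identity = identical pairs / alignment columns, a column gapped
on one side counts in the denominator and 'X' never counts as identical).
Pairs above 97% collapse the later-seen member into the earlier one
(deterministic first-by-input-order representative — which copy survives is
otherwise arbitrary); pairs below 20% contribute no edge; the surviving
edges fragment the candidates into connected components (singletons stay as
singleton groups), and the component maximizing the mean over references of
the best member identity is selected. The 20/97 bounds are treated as
percent identity: the "identical sequences" gloss on the high cut-off fits
identity, not a raw alignment score.

Completeness of a candidate is judged by coverage: align it to its
best-matching reference and flag it incomplete when more than 10% (default)
of the reference span is uncovered — the signature of internal deletions or
truncations from mispredicted splice sites. Extra N- or C-terminal sequence
never counts against completeness.

## UPGMA grouping and identity statistics

Distances are 100 − percent identity (column-wise over non-double-gap
columns for aligned input). UPGMA uses the standard size-weighted average
linkage with merge height d/2 and a lowest-index tie-break, so the builder
is deterministic; its merge heights are cross-checked against
`scipy.cluster.hierarchy.linkage(..., 'average')` in the tests. Bootstrap
support resamples alignment columns with replacement and reports, for each
internal clade of the reference tree, the fraction of replicate UPGMA trees
containing the same clade. Group identity summaries report mean ± SD
(population convention, n_pairs in the denominator — the figure style these
summaries emulate does not state the convention) and the value range,
within groups and between group pairs.

Robust-region selection is a transparent two-rule stand-in: a column is
good when its modal-residue fraction is ≥ 0.5 and its gap fraction ≤ 0.5,
and blocks are maximal good runs of ≥ 5 columns. Conservation-zone
segmentation smooths per-column modal-residue fractions with a centered
moving average (default window 11) and reports maximal runs above/below a
threshold, merged so labels strictly alternate. Maximum-likelihood tree
inference is deliberately out of scope; externally produced ML trees can be
supplied as Newick for reconciliation.

## Reconciliation

Gene trees are reconciled against a binary species tree by the LCA map:
M(leaf) is the leaf's species, M(v) the species-LCA of the children's
images. A node is a duplication iff it maps where one of its children maps.
Losses on edge (v, c) count the species-tree levels skipped between M(v)
and M(c), minus one for a speciation, with one extra loss when v is a
duplication descending below its mapping. The family is taken to originate
at M(root): nothing is charged above it. The test suite checks the total
D+L cost against an independent min-cost embedding dynamic program on all
small tree pairs. Unrooted trees are rooted by evaluating every edge and
returning *all* co-optimal rootings (canonically ordered), minimizing
duplications + losses. Gene-tree polytomies are rejected rather than
resolved; co-optimal polytomy resolution is a known open extension.

## Feature tracks

* **Hydropathicity.** Kyte–Doolittle scale, centered sliding window
  (default 19 residues, the transmembrane-scale convention; the window is
  config-exposed). Positions without a full window are missing; 'X' takes
  the scale's unweighted mean (−0.49).
* **Projection.** Per-residue values are placed at the alignment columns
  carrying each residue; gaps are missing. Projection is bijective and
  order-preserving on defined values.
* **Clade averaging.** A column enters a clade's profile only when fewer
  than 25% of the clade's sequences are gapped there (mask at gap fraction
  ≥ 0.25, config-exposed); means run over the defined values. Robustness of
  the downstream picture to this threshold is a property of the data, not
  assumed.
* **TM calling.** Maximal runs of unmasked columns with mean ≥ 1.0 over
  ≥ 10 columns; masked columns break runs.

## Phosphosite screen

Kinase-target prediction is a *contract*, not an implementation: any scorer
returning values in [0, 1] at Ser/Thr/Tyr positions plugs in. Two
implementations ship. The TSV adapter passes through precomputed per-residue
tables from an external predictor. The surrogate scorer — used by all
synthetic benchmarks — is a transparent position-weight matrix over a ±4
window with a basophilic consensus (Arg/Lys upstream, small residues
downstream) squashed through a logistic; its bias (−7) keeps unrelated
contexts near zero so that only near-consensus contexts clear the maximum
criterion. Trained external predictors are intentionally not re-implemented.

The screen reports an alignment column for a group when (i) more than 90%
of the group's members carry the acceptor class there — Ser and Thr are one
interchangeable class because homologous sites alternate between them
across channels, Tyr is separate — (ii) at least one member scores above
0.6, and (iii) the group-average score exceeds 0.2. The average runs over
members carrying the class (`mean_over="carriers"`, default); dividing by
the full group size instead is config-exposed because the convention is
genuinely ambiguous. Reported sites carry mean ± SD (population), the
maximum, and representative (sequence, 1-based position) labels; each
site's neighborhood can be exported as a 21-row (residues + gap)
position-frequency matrix for logo rendering.

## Synthetic families

The generator produces, under one seed, a fully self-consistent family:

* **Species tree.** Yule (pure-birth) on n = 10 species, depth normalized
  to 1 so divergence scalings are interpretable.
* **Duplication/loss families.** A birth–death process along the species
  tree (per unit branch length), every event recorded with its location;
  the surviving-leaf gene tree is returned with the leaf→species map.
  Loss-free runs are the ground truth for exact duplication-count recovery.
* **Architecture.** Sequences are concatenations of regions with
  region-specific composition and substitution-rate multipliers. The
  SLAC-like preset: 90-residue cytosolic N-terminus, ten 21-residue
  hydrophobic TMs (odd TMs conserved at rate 0.25 — the motif
  fingerprints), 15-residue linkers, 40-residue C-terminus (~475 residues
  total). The ALMT-like preset: six TMs in the N-half, then a C-half with
  alternating conserved/variable zones, a frozen Trp-Glu-Pro (WEP) anchor,
  and two extra hydrophobic segments — the TM7/TM8 signature the
  hydropathicity analysis must find. The hydrophobic composition has
  Kyte–Doolittle mean ≈ +2.8, linkers ≈ −0.6, so a 19-window profile
  separates segments from loops with margin.
* **Substitution model.** Per site, substitution probability
  1 − exp(−rate·branch); replacements are fresh draws from the region
  composition (which may redraw the same residue). No rate-matrix
  exponentials: this keeps the expected identity between two sequences at
  path length t analytic — per site, e^(−rt) + (1 − e^(−rt))·Σp² — which
  the generator inverts (Brent's method) to hit identity targets exactly in
  expectation. Empirical-matrix realism is out of scope.
* **Divergence tiers.** The gene tree is three copies of the species tree
  joined by two ancient duplications. Per-tier branch scalings are solved
  so mean within-tier identities hit 78/69/58%, and the two duplication
  heights so between-tier identities hit ≈52% (the two younger tiers) and
  ≈35.5% (across the root) — the identity regime of the three angiosperm
  SLAC-like channel groups. Within each tier the species-tree node heights
  are compressed toward the crown (`crown_spread = 0.2`, i.e. 20% of the
  height variation retained): ortholog groups radiate quickly relative to
  the ancient duplications separating them, and without compression the
  oldest tier's deepest splits would pre-date the youngest duplication,
  making the tiers structurally unrecoverable by any clustering.
* **Planted sites.** Group-specific phosphosites are written into the root
  sequence with the surrogate scorer's consensus context (KRRQ·GPEE), the
  ±4 window frozen (rate 0); carrier tiers keep the acceptor, non-carrier
  tiers have it replaced by Ala at the tier root. The SLAC preset plants
  sites emulating the observed pattern: an N-terminal cluster, one inter-TM
  linker site, and a proximal C-terminal site, shared between tiers in
  several cases.
* **Decoys.** Screen negatives drawn i.i.d. from a uniform composition,
  same length as the family; the default preset ships 3×10 members + 5
  decoys.

v1 is indel-free, so the true alignment is the trivial column map and all
truth tables use fixed alignment coordinates. What passing tests therefore
show about real data is limited: no alignment uncertainty, no fragmentary
gene models, no compositional heterogeneity beyond the planted
architecture, and sequence divergence that is calibrated rather than
empirical. The tests demonstrate that each analysis rule does exactly what
it claims under known truth — not that the rules are robust to the noise
sources the original genome-scale analysis faced.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; benchmark bundles are
byte-identical across runs with the same config (the bundle manifest hashes
the config and contains no timestamps). Bundles are written atomically
(staging directory, then rename). The shipped analyses use families of 30
sequences × ~450 residues, 8–10-species trees, 100–1000 bootstrap or
calibration replicates — sizes chosen so every stage's behavior is
measurable against truth while the whole analysis reruns in minutes on one
CPU. Genome-scale inputs (dozens of proteomes) and the counts that depend
on them are outside what the synthetic conditions can or should reproduce.

## Known limitations

* Single-hit glocal HMM scoring only; proteins carrying two copies of one
  motif are scored by their best copy.
* ClustalW's exact score rounding is not reproduced; the 20/97 curation
  bounds act on standard percent identity.
* Reconciliation handles duplications and losses only — no transfers, no
  bootstrap-weighted rearrangement, no dated reconciliation.
* The GBlocks-style block selector is a two-rule surrogate, not the
  original heuristic.
* The surrogate phosphosite scorer is a fixed PWM, suitable for exercising
  the screen's logic, not for predicting real kinase targets; real use goes
  through the table adapter.
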