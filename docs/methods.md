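# Methods

This note documents the models, parameters and numerical choices behind
`colnet`, and what the synthetic data does and does not establish.

## Confidence-filtered sequence preparation

A predicted-model PDB file carries one pLDDT confidence value per residue in
the B-factor column; the parser takes the B-factor of a residue's *first*
atom (predictors write identical values on all atoms of a residue, so this is
robust to truncated records) and rounds it to two decimals, the resolution of
the PDB B-factor field.  Only single-model, single-chain files are accepted;
unknown residue names map to `X`.

Feature tables use the UniProt convention (1-based, inclusive); conversion to
the internal 0-based half-open convention happens once, in
`seq_io.read_annotations`.  The three conditions are WHOLE SEQUENCE
(identity), WITHOUT SIGNAL (signal-peptide interval removed) and ONLY CHAIN
(signal and all propeptides removed).  Chains lacking a required annotation —
transmembrane collagens have no signal peptide — pass through unchanged with
a logged warning rather than an error, so a heterogeneous chain set can be
processed under one condition.  Residue-level PTM rows (e.g. proline
hydroxylation) are accepted in the table and ignored; only region-level
features participate in the conditions.

## Greedy extraction

Parameters: window length L (grid 10–500 step 10, default 30) and confidence
threshold γ ∈ [0, 100] (grid 0–95 step 5, default 70; 70 is the conventional
"good backbone prediction" boundary for pLDDT).  Each round selects the
length-L window with maximal mean confidence, emits it if the mean is ≥ γ
(≥, so γ = 0 keeps everything), and overwrites its confidence entries with
the sentinel −1×10⁹.  Because the sentinel dominates any window mean that
touches it, emitted windows are provably disjoint and the emission-time means
are non-increasing.  Tie-breaks go to the leftmost window; windows containing
`X` are ineligible (their positions are treated as sentinel-valued), since
the hydrophobicity of an unknown residue is undefined.  Output is in
extraction order; a position sort is available.  Each forward subsequence is
paired with its plain string reversal ("reversed" — a protein has no
complement), marked `rev` in the FASTA name.

## Substitution matrix

The packaged Eisenberg consensus scale assigns each amino acid a
hydrophobicity in kcal/mol (glycine 0.48, proline 0.12, extremes isoleucine
1.38 and arginine −2.53).  Scores are s(a,b) = round(20·(1 − Δ(a,b)/Δmax)):
the inversion is required for the stated ceiling (identical sequences must
score the maximum, 20); Δmax is the theoretical maximum difference over all
190 residue pairs of the scale (not an observed-data min–max, a deliberate
choice so the matrix is dataset-independent); rounding is half-away-from-zero
("to the next integer").  Any 20-entry user scale can be substituted; an
all-equal scale is rejected as degenerate.

## Alignment and normalization

Global alignment uses Gotoh three-state dynamic programming with affine
gaps: a gap of length k costs open + (k−1)·extend with open = 10 and
extend = 0.5 (the EMBOSS defaults; the alternative convention
open + k·extend is available via `GapParams.extend_on_open`).  End gaps are
free by default (EMBOSS endweight=false) but still appear as columns of the
reported alignment; a flag penalizes them.  Traceback is deterministic with
tie preference diagonal > up > left, and the end cell for free end gaps is
chosen corner-first, then last row right-to-left, then last column
bottom-to-top.  All intermediate scores are multiples of 0.5 and hence exact
in double precision, so traceback equality tests are reliable.  The
normalized similarity is the raw optimum divided by the number of alignment
columns (end-gap columns included), bounded by 20 and attained exactly by
identical sequences.

Reversal invariance (similarity(rev a, rev b) = similarity(a, b), a
consequence of the symmetric scoring) is exploited to skip
reversed-vs-reversed pairs in the all-vs-all pass; a record against its own
reversal is scored.

## Compression, networks, sweep

Chain- and collagen-level matrices take the maximum similarity over all
scored record pairs between the two groups; a group with no scored
within-group pair gets the conventional self-similarity 20 on the diagonal,
which never generates edges.  Network edges require similarity ≥ τ
(inclusive, so "the lowest threshold with a property" is well defined); the τ
grid is the half-open [12, 20) in steps of 0.25 — 32 values, matching the
published grid cardinality; an inclusive 33-value variant is available.
Subnetworks are connected components with ≥ 2 nodes; isolated nodes are
reported separately, following the convention that unconnected chains are
listed apart from the subnetworks.  Labels are ordered lexicographically
everywhere so repeated runs produce byte-identical files.

The full grid (3 conditions × 50 lengths × 20 confidence thresholds × 32
network thresholds × 2 levels) enumerates 192,000 network configurations;
`run_sweep(dry_run=True)` enumerates the manifest without computing, and the
operating-point statistics (`grid_statistics`) report per-cell subsequence
counts and the population standard deviation of the pairwise similarities.
No selection rule is hard-coded for the "optimal" cell: the published
optimum balances subsequence count against score spread without a stated
formula, so the package reports both quantities plus a Pareto front
(maximizing both) and leaves the choice to the user.

## Literature reference matrix

Hit counts h (symmetric, diagonal = single-term hits) transform as: h = 0 ↦
10 (the published zero-occurrence convention) and h > 0 ↦
S·(1 − log₁₀₀(h)/log₁₀₀(h_max)) with S = 10, which is strictly decreasing in
h and maps the best-studied pair to 0.  The published example values cannot
all be reconciled with a single log-then-min-max formula, so only the
zero-hit convention and the monotonicity are treated as fixed; base, scale
and zero-value are explicit parameters.  Note the corner cases: h = 1 maps
to S itself (equal to the zero-hit value at defaults), and a matrix whose
largest count is 1 maps all nonzero cells to 0.  Edges in literature
networks use distance ≤ τ (default τ grid 1..20 step 1) — the mirror of the
similarity networks, because lower distance means more co-occurrence.

## Synthetic data: what it emulates and what it does not

Each of six families (mirroring the six collagen groups, 44 chains total
with 11/9/8/7/5/4 per family) owns a 30-residue ancestor motif drawn from a
family-specific hydrophobicity band of the Eisenberg scale:
{I,F}, {M,A}, {T,S}, {K}, {E,Q,N,D}, {R}.  Bands are spaced so that, under
the packaged matrix, aligned cross-band columns score ≈ 16–17 while
within-family motifs (independent copies of one ancestor mutated at rate
0.02 per position) score ≈ 19–20; the default network threshold 17.5
therefore sits in the designed separation gap.  Chains are assembled as
[signal 20][flank with motif 30][(G-X-Y)₈₀ core][tail 30]; motif positions
draw confidence from N(90, 3²), everything else from N(30, 8²), clipped to
[0, 100] and rounded to two decimals so tracks survive a PDB round trip.
The fibrillar-like family carries its motif in the N-propeptide (so ONLY
CHAIN eliminates it — the propeptides are essential for the comparison, as
with real fibrillar collagens); the transmembrane-like family has no signal
peptide.  Mutations are substitutions only by default so the designed
similarity levels stay analytically controllable; an indel mode exists
behind `indel_rate`.  Hit counts are Poisson with within-family means
boosted 10× over between-family means and diagonals above everything.

Passing tests on this generator establish that the pipeline's machinery —
filtering, scoring, compression, thresholding — recovers planted structure
with the documented guarantees.  It does not establish biological
conclusions about real collagens: real pLDDT tracks are smooth rather than
i.i.d. noise, real motifs are not hydrophobicity-homogeneous, and real
family separations are narrower and threshold-sensitive.

## Problem sizes used in the test and acceptance runs

Alignment correctness is checked exhaustively against alignment enumeration
for all sequence pairs up to length 3 over {G,P,I,R} and by seeded sampling
at lengths 4–5 (enumeration grows as the Delannoy numbers, so exhaustive
length-5 is not informative per unit cost), plus a 100-pair cross-check
against an independently configured reference aligner; extraction is checked
against a brute-force re-scan on sequences up to 40 residues; end-to-end
recovery runs the full default dataset (44 chains, 2882 scored pairs).

## Known limitations

- The aligner is pure-Python O(mn) per pair; at the largest grid lengths
  (L = 500) a full sweep is compute-heavy.  Scores are exact, so a faster
  backend can be swapped in without changing results.
- mmCIF models, predicted-aligned-error matrices and structure geometry are
  out of scope; only the B-factor confidence track is read.
- Live literature querying is out of scope; hit counts arrive as a table.
- GML parse errors surface with networkx's diagnostics rather than exact
  line numbers.
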