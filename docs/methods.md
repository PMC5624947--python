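# Methods

This note documents the models and procedures implemented in `memsa`, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not show.

## Topology prediction

The predictor is a hydropathy-window method. Each residue gets the mean
Kyte-Doolittle index over a centred window (default 19 residues, truncated
at the sequence ends); maximal runs of windowed hydropathy ≥ 1.6 are
candidate helices. Window 19 matches the physical span of a membrane
helix; 1.6 on the Kyte-Doolittle scale is the classic operating point at
which windowed averages separate membrane-like from soluble stretches.

Window averaging blurs boundaries by up to half a window, so each run is
refined on the **raw** per-residue values: within the run expanded by half
a window per side (capped at the midpoint to any neighbouring run), the
helix is taken as the maximal-sum interval of `KD(residue) − δ` (Kadane's
algorithm, leftmost on ties). The margin δ (`boundary_delta`, default 2.2)
sits between cysteine (2.5) and methionine (1.9) on the Kyte-Doolittle
scale: only the five most hydrophobic residues (I, L, V, F, C) pull a
boundary outward, while the ambivalent A and M cannot drag it into a loop.

Refined runs shorter than `min_helix_len` (15) are discarded; runs longer
than `max_helix_len` (35) are split by removing their lowest-scoring
interior *stretch* — the minimal-sum subinterval of the margins, which is
the polar loop that the window smoothed over when two helices sit close —
and reprocessing both sides. A uniformly hydrophobic over-long interval
(no negative stretch) is halved at its centre, sacrificing the middle
residue as a one-residue loop. Splitting at a stretch rather than a single
position matters: a point cut misplaces *both* flanking boundaries when a
bridging loop is several residues wide.

Hydropathy cannot determine which side of the membrane the N-terminus is
on, so loop labels alternate `outside`, `inside`, … from the N-terminus.
The aligner treats the two loop classes identically; orientation affects
only the TM-Info report. Imported annotation files override prediction.

## Region-wise progressive alignment

Sequences are grouped by predicted TM count; the largest group is the
dominant class (ties go to the larger count, which anchors more columns).
Its shared count K fixes 2K+1 region slots. One UPGMA guide tree, built
from 3-mer fractional distances on the full-length sequences, is reused
for every slot: the tree encodes sequence relatedness, which does not
change from region to region.

**Boundary harmonization.** Before the slots are aligned, helix boundary
calls are made consistent across the dominant class. Per-sequence
prediction places each boundary independently, so homologous helices
typically disagree by a residue or two of trim or overhang; region-wise
alignment would then put those edge residues into different region slots,
where no alignment step can ever pair them. Since TM helices are conserved
blocks within a family, the class itself is the best boundary evidence:
each TM slot is pre-aligned semi-globally, the window of columns occupied
by a majority of members is taken as the family's helix extent, and each
member's boundaries are adjusted to that window (overhanging residues are
pushed back into the flanking loop; in-window gaps pull the adjacent loop
residues in, never emptying an interior loop). The step is deterministic
and uses only the input sequences.

**Dynamic programming.** All alignment uses the Gotoh three-layer affine
recurrence (substitution layer plus one layer per gap direction) over
integer scores. Each layer carries a branch matrix of the same
(m+1)×(n+1) shape storing the transition that produced each cell, so one
optimal alignment is recovered by walking the branch matrices without
recomputation. Traceback ties prefer substitutions, then gaps in the
second input — deterministic output. A gap of length L costs
`open + (L−1)·extend`; the published defaults are open 8, extend 1.

TM slots are aligned **semi-globally** (leading/trailing gaps free):
residual one-to-two-residue boundary disagreements then shift the register
instead of forcing an off-register gapless alignment of equal-length helix
strings. Loop slots are aligned **globally**: their length variation is
genuine indel history and terminal gaps there are real events. Profile
columns are scored as the average substitution score over all residue
pairs between the two columns (gaps contribute zero to the numerator; the
denominator is the product of the profile sizes); the implementation runs
the DP on the integer numerators with gap penalties scaled by the same
product, which is exactly equivalent and keeps every comparison integer.

**Matrices.** TM regions default to PHAT, loops to BLOSUM62; `--matrix`
forces one matrix everywhere. PHAT was built from transmembrane blocks and
rewards the hydrophobic substitutions common inside the bilayer; loops are
soluble-like, hence BLOSUM62. Whether the original default applied PHAT to
loops as well is not documented, so both behaviours are reachable through
configuration. GONNET250 entries are stored ×10 and rounded so the DP
stays integer-exact. The bundled PHAT table is this package's
transcription of the PHAT(75/73) transmembrane matrix; users who need
entry-for-entry parity with another distribution should verify the table
(`src/memsa/data/phat_75_73.txt`, documented plain-text format) against
their source. Tests pin only its structural properties (symmetry,
completeness, hydrophobic-over-polar preference), not individual entries.
BLOSUM62 and GONNET250 are taken from Biopython's published tables. The
unknown residue X scores 0 against everything.

**UPGMA.** Clusters merge at height d/2 with size-weighted average
distance updates. A per-row reference to each row's minimum entry makes
every merge O(N) — O(N²) overall instead of O(N³) — and the
implementation is result-identical (topology and heights) to the naive
full-scan algorithm under the shared tie-break: lowest (i, j) pair in
row-major order.

**Stitching.** The full-length seed alignment is the horizontal
concatenation of the slot alignments in topology order; columns inherit
their slot's TM/loop label. Before concatenation, each member's degapped
slot rows are re-located in its original sequence by Wu-Manber
multi-pattern matching and must form a contiguous left-to-right tiling;
any failure indicates corrupted segmentation and aborts the run. All-gap
columns are stripped only at the very end, so intermediate widths stay
consistent across slots.

**Off-class sequences** (TM count ≠ K) are aligned to the seed profile as
whole sequences, one at a time in order of increasing 3-mer distance to
the seed consensus, using the TM matrix (the default overall matrix).
Only whole gap columns are inserted into the seed, so the relative gap
placement among seed columns — in particular within TM blocks — is never
modified; columns introduced by these merges are labelled `mixed`. If the
dominant class has zero helices the run falls back to plain progressive
alignment of all sequences with the loop matrix, with a warning.

## Wu-Manber matcher

Preprocessing builds SHIFT, HASH and PREFIX tables over blocks of size
S ∈ {2, 3} with match window m = the shortest pattern length: a block
ending at position j within a pattern's first m characters gets shift
m−1−j (minimum across patterns), absent blocks get the default m−S, and
zero-shift blocks carry HASH candidate lists verified first by their
S-character PREFIX and then by full comparison. Blocks are addressed by
their literal string through a dict, which preserves the shift/filter/
verify behaviour while making hash collisions moot. Patterns shorter than
S cannot index the tables and are found by a naive scan merged into the
hit list. Exactness is tested against a quadratic reference scanner on
randomized pattern/text sets.

## Scoring an alignment against a reference

`sp_score` counts residue pairs: for every pair of sequences and every
reference column where both have residues, the pair enters the
denominator, and enters the numerator when the two residues also share a
column in the test alignment. Columns with gaps contribute only their
residue-residue pairs; identity of degapped sequences between test and
reference is enforced. The consensus string reports, per column, the
symbol (gap included) whose frequency strictly exceeds the majority
fraction (default 0.5), else `X`.

## Synthetic families

The generator draws an ancestor with K helices (lengths 18–25) separated
by loops (lengths 5–40), helices from a hydrophobic pool weighted toward
I/L/V (mean KD ≈ +3.6), loops from the full alphabet biased polar (mean
KD ≈ −0.9). Descendants apply i.i.d. substitutions per site — helix
substitutions stay inside the hydrophobic pool, as membrane constraints
demand — and at most one indel per loop per descendant (probability 0.3,
geometric length with mean 3, deletions never emptying a loop). The true
alignment is built from the edit history; insertions private to one
descendant get their own columns rather than being aligned to other
descendants' insertions, since unrelated insertions carry no homology
signal. The default substitution rate 0.34 was calibrated by direct
measurement to give ~50% mean pairwise identity, the benchmark's stated
difficulty; `measure_identity` reports the realized value of any family.

What the benchmark shows: at the difficulty where full-length aligners
typically disrupt helices, the region-wise method reconstructs ≥ 0.9 of
true residue pairs on average with indel-free TM columns. What it does not
show: performance under tree-structured (non-star) evolution, rate
heterogeneity, helix indels, signal peptides, re-entrant loops, or real
topology-predictor error profiles — the generator's loops and helices are
compositionally cleaner than real proteins, so real-data accuracy will be
lower and should be assessed against curated reference alignments.

## Degenerate inputs and edge cases

Sequences whose region list starts or ends with a helix get empty
terminal loop strings, which travel as zero-width profile rows and become
all-gap rows. A dominant class of one member skips tree building and uses
its regions directly as the seed. Duplicate ids, residues outside the
20+X alphabet, annotations that do not tile the sequence, and guide-tree/
input mismatches all fail fast with messages naming the offender. The
input-count guard (`max_seqs`, default 5000) mirrors the historical
server-load cap and can be disabled with 0.

## Known limitations

Single-sequence hydropathy prediction has a noise floor: genuinely
hydrophobic loop clusters adjacent to a helix can legitimately pull a
predicted boundary a few residues outward, so ~4% of synthetic helix
boundaries miss the truth by more than 3 residues even after refinement;
boundary harmonization absorbs most, but not all, of the consequence for
alignment accuracy. No iterative refinement or consistency scoring is
performed by design — the method is single-pass progressive. Orientation
(inside vs outside) is reported by convention, not predicted.
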