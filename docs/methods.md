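# Methods

## Family criterion and motif model

A protein belongs to the IQD/SUN family iff it contains an IQ67 domain:
three IQ motifs whose two inter-motif spacers are exactly 11 and 15
residues. Motifs are fixed-width consensus windows:

| class | pattern | width |
|---|---|---|
| strict IQ | `IQXXXRGXXXR` | 11 |
| relaxed IQ | `[ILV]QXXXRXXXR[RK]` | 11 |
| 1-8-14 | `[FILVW]X6[FAILVW]X5[FILVW]` | 14 |
| 1-5-10 | `[FILVW]X3[FILV]X4[FILVW]` | 10 |

Matching is per-position set membership. An `X` in a *sequence* satisfies
wildcard positions only, never a constrained class — permissive I/O,
conservative matching. All overlapping windows are reported; a window
satisfying both IQ consensi is labelled strict only. Spacing counts
residues strictly between one motif's end and the next motif's start —
the only convention under which "11 and 15" is a checkable criterion
(note three 11-residue motifs plus 11+15 spacers span 59 residues; the
domain's traditional "67" name is not enforced, the computed span is
reported). Every valid triple is reported; the family call uses existence,
not uniqueness. Accessory 1-8-14 / 1-5-10 motifs overlapping the domain
span are counted but not required, since family descriptions say the
domain *usually* contains them; `require_accessory`-style filtering is
deliberately left to the caller. Relaxed IQ matching is on by default and
both modes are exposed, since published identifications list both consensi
without stating which was decisive.

Coordinates are 0-based half-open internally, 1-based inclusive in all
emitted tables. DUF4005 annotation is reserved as an empty column: no
consensus is available to scan for.

## Physicochemistry

Molecular mass is the sum of average (not monoisotopic) residue masses
plus one water, the ProtParam convention. Net charge at a given pH is the
Henderson–Hasselbalch sum over the termini and the D, E, C, Y, K, R, H
side chains using the Bjellqvist pKa set, including the residue-specific
N- and C-terminal corrections (the table is a versioned constant in
`protparam.py` and can be swapped). The theoretical pI is the bisection
root of the net charge on [0, 14], default tolerance 0.001 pH — the
charge function is strictly decreasing in pH, so bisection is exact up to
tolerance. One consequence of the terminal corrections worth knowing:
appending a glutamate to a strongly acidic peptide can *raise* the pI
slightly, because the C-terminal pKa shifts from 3.55 to 4.75 when E
becomes the terminal residue; the usual "acids lower pI" intuition holds
for peptides with pI above ~5.5.

ORF arithmetic: a coding span of `bp` nucleotides including the stop codon
encodes `bp/3 − 1` residues. Reported summaries round half-up — pI means
to 2 decimals, masses to 0.1 kD, percentages to 1 decimal — mirroring how
such tables are usually printed.

## Phylogeny

Distances are p-distances (mismatches over gap-free sites; default) or
Poisson-corrected −ln(1−p), with pairwise gap deletion by default and
complete deletion by flag. Neighbor joining follows Saitou–Nei with the
standard Q criterion and Studier–Keppler branch lengths; Q ties break on
the lowest (i, j) index pair so runs are deterministic. A negative branch
length is clamped to zero and the deficit moved to its sibling, preserving
leaf-to-leaf path lengths; on additive matrices NJ is consistent, and the
tests verify exact topology and path-length recovery up to 12 taxa.
Bootstrap resamples alignment columns with replacement, rebuilds the tree
per replicate, and labels each internal split of the original tree with
its replicate frequency × 100. Trees are scikit-bio `TreeNode`s;
serialization is Newick with supports as internal labels. Clade labels
(the I–V of published figures) are user annotations, not computed — no
algorithmic clade definition exists to implement.

## Gene structure

GFF3 parsing (gffutils, in-memory) takes the first mRNA per gene by
default (longest-isoform selection by flag) and orders exons in
transcription order: ascending coordinates on `+`, descending on `−`.
Published short/medium/long assignments are qualitative, read off
structure diagrams, so the bins here are explicit absolute thresholds —
exon length ≤ 200 bp is short, ≤ 600 bp medium, above that long —
recorded in output metadata and configurable. Pattern labels are not
invariant under uniform length rescaling unless the thresholds are
rescaled identically; this is intentional, since the published patterns
are about absolute exon sizes.

## Quantification

Heatmap preparation is elementwise log2(x+1) with optional per-gene
z-scaling (population sd; constant rows map to zero). 2^−ΔΔCt averages
technical replicates first, then forms ΔCt = Ct_target − Ct_reference and
ΔΔCt against the calibrator sample's mean ΔCt per biological replicate;
the calibrator's fold of its mean ΔΔCt is exactly 1. Group comparisons
use Welch's unequal-variance t (two-sided) with the conventional star
thresholds (p strictly below 0.05/0.01/0.001/0.0001). Multi-group letters
use Holm-adjusted pairwise Welch tests and an insert-and-absorb compact
letter display, chosen over Tukey HSD because the published figures never
name their procedure and the Welch/Holm combination makes no
equal-variance assumption; groups share a letter iff the adjusted test
does not separate them (an oracle test asserts exactly this equivalence).
The FSI-on-expression relation is ordinary least squares with
R² = 1 − SSres/SStot.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *structure* of a real family survey with
known truth. Family proteins (default 24, lengths 261–845 aa) carry one
planted IQ67 block — three strict IQ motifs with 11/15 spacers — at a
recorded offset, in a K/R-enriched background composition giving the high
pI typical of the family; decoys (default 9, lengths 744–1523 aa,
D/E-enriched) carry 1–3 IQ motifs with spacings offset by ±1–5 residues,
the near-miss regime of Myosin/CaMTA proteins; backgrounds are
rejection-sampled until they contain zero IQ windows, which makes scanner
specificity testable at exactly 100% rather than approximately. Planted
and decoy sequences are likewise rejection-sampled until their realized
IQ hits are exactly the planted ones, so truth tables are consistent with
the emitted FASTA by construction.

Gene models realize the named exon patterns with 4/10/3 members plus 7
unnamed 2- or 4-exon genes on both strands. Alignments evolve a uniform
random root sequence along a tree with Poisson(rate × branch length)
substitution events per site, redrawn uniformly over 20 residues — a
deliberately simple model whose saturation p-distance is 0.95. Ct tables
encode fold changes exactly in expectation (Ct_target = base − log2(fold))
with biological and technical replicate noise of 0.08 cycles each,
realistic for a well-expressed target and small enough that the fold is
recovered within 10% from three biological replicates. Fruit tables draw
per-fruit FSI ~ N(line mean, 0.08) applied to a shared stage-dependent
horizontal-diameter distribution (lines default to wild type 1.09 and
overexpression lines 1.23/1.21, n = 40 per line); the FSI-expression
scatter sets its residual sd from the realized predictor variance so the
expected R² equals the configured 0.76.

What the generators do *not* emulate: real substitution matrices (no
BLOSUM), indels, paralog-specific conservation gradients across the three
IQ motifs, UTRs and alternative isoforms, RNA-seq read-level noise, or
correlated multi-stage fruit growth. Passing the recovery tests therefore
demonstrates correctness of the algorithms under clean, known-truth
conditions — not performance on degraded real annotations.

At the study's sample sizes (n = 40 fruits per line, sd 0.08), a single
simulated experiment recovers the planted percent-FSI increase with a
standard error of about 1.5 percentage points; the acceptance script
therefore averages the estimator over 20 replicate experiments (each at
the stated per-experiment conditions) to report the planted effect with
small Monte Carlo error, and similarly for qPCR folds and the scatter R².

## Numerical and degenerate-input conventions

Sequences are uppercased and one trailing `*` stripped on load; any other
non-residue character is an error naming its 1-based position. Empty
FASTA scans yield empty tables. NJ with two taxa returns the single edge
(split across the two leaf branches); a pair with no gap-free shared
columns, or a Poisson distance at p = 1, is an error rather than an
infinity. Zero-variance predictors are an error in the regression;
degenerate (n < 2) groups are an error in all tests. All generators and
the bootstrap take explicit seeds; identical seeds give byte-identical
outputs.

## Problem sizes

Default test and analysis runs use the 133-protein synthetic proteome,
24 gene models, 300-site alignments over ≤ 12 taxa, 100–200 bootstrap
replicates, and 10–20 replicate simulated experiments in the acceptance
script — sizes chosen so the whole suite runs in seconds while every
statistical check retains comfortable margins.
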