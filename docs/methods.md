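# Methods

This note documents the models, conventions and numerical choices behind
`cpbarcode`, in the order the pipeline runs them.

## Quadripartite structure detection

The detector searches for the longest pair of disjoint intervals on the
circular genome whose sequences are exact reverse complements, by
seed-and-extend over a k-mer index (k = 21) on the doubled sequence, with
matches grouped by their antidiagonal invariant so each maximal match is
extended once. One antidiagonal can carry several separate matches —
including boundary-truncated echoes of a repeat that wraps the origin —
so seeds are skipped only when a previous extension on the same
antidiagonal already covered them. Exactness (no mismatches) is
deliberate: plastome IR copies are near-identical in practice, and an
exact criterion gives testable, reproducible junctions. A genome with no
disjoint reverse-complement pair of at least `min_ir_len` (default
1000 bp) is reported as non-quadripartite; the tool never infers whether
an IR is biologically absent or merely unannotated.

Ties between equal-length candidate pairs are broken toward the most
balanced single-copy split, then by position. The longer single-copy gap
is labelled LSC. Coordinates are reported on a canonical orientation
(LSC, IRb, SSC, IRa starting at the IRa/LSC junction) with the rotation
offset retained, so detection is rotation-invariant by construction and
verified by test. SSC orientation isomers are reported as found, not
standardised.

## Repeat profiling

**SSRs.** A locus is a maximal perfect tandem run of a 1–6 bp motif whose
whole-copy count meets its period's threshold. Defaults are
25/15/2/2/2/2 copies for mono- through hexanucleotides; a `misa-defaults`
preset (10/6/5/5/5/5) is also shipped. Copy thresholds of 2 for periods
3–6 are extremely permissive — any 6 bp tandem qualifies — so random
sequence yields mostly trinucleotide loci (~72% in the synthetic
ancestor); that behaviour is intentional under the default preset.
Conventions: each run is reported once under its smallest period (a
homopolymer is never a period-2 locus; enforced via the minimal period of
the run's span); runs split at N; compound/interrupted repeats are not
merged; same-period runs never overlap (when two maximal runs share up to
period−1 bases, the left one wins). Correctness is checked against an
independent brute-force scanner on randomized instances.

**Long repeats.** All maximal exact repeated pairs ≥ 30 bp at 100%
identity, direct and inverted, found by seed-and-extend with seeds of the
minimum length, grouped by diagonal (direct) or antidiagonal (inverted).
Direct occurrences may overlap (tandem duplications). Inverted
occurrences are kept disjoint: extension stops where the two arms would
meet, so a perfect palindrome is reported as its two halves — this is
what makes the IRa/IRb pair itself appear as one full-length inverted
record, which is flagged as the structural IR. Occurrence A precedes
occurrence B by start position. Oracle: an O(L²) dot-plot diagonal scan.

**Summaries** count per region (LSC/IRb/SSC/IRa) by midpoint, one count
per genome copy (IRa and IRb hits counted separately).

## Nucleotide diversity and hotspot screening

Annotated CDS and intron features are lifted into alignment coordinates
gap-aware (reference position p → column of the p-th non-gap reference
character); intergenic spacers are derived between adjacent genes and
named "geneA-geneB" (upstream gene first); zero-length spacers are
dropped with a log note. π is the average pairwise difference per
compared site. Default gap policy is complete deletion (columns with any
gap or N removed first), the common default of alignment-polymorphism
software; pairwise deletion is exposed as an alternative. N is treated
as missing everywhere. IR-duplicated content should be counted once — in
practice the IRb gene copies carry an `_IRb` suffix so IRa-side regions
can be selected.

Hotspot thresholds are inclusive: CDS π ≥ 0.00015, intergenic/intron
π ≥ 0.0001 (`default` preset); a `strict` preset carries the alternative
pair 0.00017/0.00012. Introns are screened with the intergenic threshold,
since intron markers group with the non-coding loci in practice. Tables
print π to 5 decimals; records keep full precision. Note that the
published thresholds are tuned to between-accession divergence in a real
genus; on synthetic clades at the default base rate nearly every region
exceeds them, so ranking (not the binary flag) is what the hotspot-
recovery experiments score.

## Marker design

Around each hotspot's variable span (its non-conserved columns), the
designer enumerates fully conserved windows of primer length (18–25 nt)
upstream and downstream. Column conservation is 1.0 only when a column
has no gap and a single non-N residue; a gap breaks conservation, N does
not. Windows pair into a candidate when every accession's ungapped
product — forward 5′ end through the reverse-binding-site 3′ end — lies
in 250–1500 bp. Candidates are ranked by variable columns covered
(descending), then maximal product length (ascending), then forward/
reverse Tm gap. Enumeration sweeps reverse windows nearest the hotspot
first and, per reverse window, forward ends leftward until the product
bound is provably exceeded, which keeps the search linear in flank
length.

Tm uses the Wallace rule 2(A+T) + 4(G+C) — a deliberately simple,
rank-consistent model; no nearest-neighbor thermodynamics, dimer or
hairpin screening. GC outside 35–65% is logged, not rejected. The
reported annealing temperature is the configured bench target (54 or
58 °C) closest to min(Tm_f, Tm_r) − 5 °C; it is a labelled heuristic, not
a thermodynamic prediction. Degenerate bases are never emitted:
conservation must be absolute within the input panel.

## Identification statistics

Per-locus alignments are trimmed (default: drop any column containing a
gap or N; a gap-fraction policy is exposed) and concatenated in a fixed
locus order with a partition map. Distances: p-distance with pairwise
deletion; Jukes–Cantor −(3/4)ln(1 − 4p/3) (error at saturation); Kimura
two-parameter from transition/transversion counts. Neighbor-joining uses
the standard Q criterion with lexicographic tie-breaking and
negative-branch clamping to zero; it is consistent on additive matrices
(verified exactly) and cross-checked against scikit-bio's implementation.
NJ serves as the deterministic in-repo surrogate for likelihood/Bayesian
tree building, which is out of scope; externally computed Newick trees
can be supplied to the tree-based statistic instead.

"Identified" is operationalised two ways. `haplotype_unique` (default):
an accession is identified iff no other accession has an identical
sequence after the complete-deletion mask — this makes every reported
rate exactly 100·k/n, matching the k-out-of-n structure of published
rates, and is provably monotone under adding loci. `tree_singleton`: the
accession's terminal branch is positive and it shares no zero-length
cherry/polytomy with an identical-haplotype accession. Rates are rounded
half-up to two decimals.

## Synthetic clade generator

The generator is the ground-truth instrument, not a realism engine.
Defaults mirror the study conditions: an ancestor of 80 014 + 21 552 +
12 791 + 21 552 bp (135 909 total) at GC 0.38 with a representative
91-gene complement, and 44-accession clades. Trees are Yule (pure birth)
with depth normalised to 1, so `base_rate` reads directly as expected
root-to-tip substitutions per site; the default 0.002 puts pairwise
divergence in the 10⁻³–10⁻² range seen between congeneric plastomes.
Substitutions follow Jukes–Cantor applied site-wise per branch
(p_change = ¾(1 − e^(−4d/3)), changed sites uniform over the other three
bases) with per-region rate multipliers addressable by structural label,
gene name or spacer name. IRb is emitted as the exact reverse complement
of IRa, and planted SSRs/repeats are flank-blocked so detectors recover
them as maximal; junctions are likewise blocked so structure recovery is
exact. Identical groups are enforced by copying the first member's
sequence (and indel events) to the group, emulating shared maternal
lineages. Indels, off by default, are geometric-length (p = 0.5) events
confined to intergenic sequence, so CDS frames and gene coordinates
survive; insertions open private gap columns rather than being
re-aligned. Truth output records the tree, per-region multipliers,
realised haplotype classes, and per-taxon divergence from the ancestor
per region (realised site differences, not event counts).

What the generator does not emulate — rate heterogeneity within regions,
IR boundary shifts, recombination, codon structure, alignment error —
bounds what passing tests show: they validate the statistics and the
pipeline logic, not performance on real GenBank panels, which depends on
alignment quality and accession versioning.

## Problem sizes and determinism

Tests and the acceptance script use scaled-down instances chosen as the
package's own test conditions: ancestors of 8–14 kb with ~15–24 genes for
per-module checks, 20-taxon/50-replicate hotspot-recovery experiments,
a 44-accession clade for identification semantics, and the full
135 909 bp ancestor wherever structure magnitudes matter. All randomness
flows from explicit integer seeds (numpy `default_rng`); reruns are
byte-identical, and the oracle suites re-derive every expected value from
independent brute-force implementations at run time.

## Known limitations

Mismatch-tolerant IR detection is not implemented (`max_mismatch_frac`
must be 0). Imperfect/approximate repeats and tandem periods above 6 are
out of scope. The marker designer does not do in-silico PCR against
mismatched templates. The tree-based identification rule depends on the
NJ surrogate's zero-branch geometry where a published study would use a
likelihood tree; both statistics are therefore always labelled with their
method in output.
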