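# Methods

This note documents the models, conventions and numerical choices behind
mitocomp, and what the synthetic-data generator does and does not
emulate.

## Genome model

Features carry 1-based inclusive coordinates on the heavy strand, the
convention of GenBank and of published mitogenome annotation tables.
Light-strand features keep H-strand coordinates; "coding-strand
sequence" means the reverse complement of the H-strand slice, which is
what reproduces the characteristic compositions of L-encoded genes
(T/G-rich ND6, A-rich L-strand tRNAs).  Sizes are always recomputed as
`end − start + 1`; a declared size column is cross-checked and
mismatches warn rather than silently correcting.  Origin-spanning
features are not modelled (none occur in the canonical teleost layout);
the `circular` flag is reserved and the spacer census can optionally
close the circle.

Spacer/overlap classification uses genome order and ignores strand,
because annotation tables report a single intergenic column: a
consecutive pair with gap g > 0 is a spacer of g bp, g < 0 an overlap of
−g bp, g = 0 adjacent.  Only overlaps of length > 0 are counted as
overlaps.

## Composition, skews, codons

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed from raw counts;
N bases are excluded from denominators (a warning fires above 10% N).
A skew whose denominator is zero is reported missing, never as 0.
Display rounding is half-up — 1 decimal for percentages, 3 for skews —
and is applied only at the display layer; all internal arithmetic is
full precision.

Stop classification follows gene length mod 3: 0 → complete stop
(legal set TAA/TAG/AGA/AGG under the vertebrate mitochondrial code),
2 → `TA-`, 1 → `T--`; the truncated stops are completed to TAA by
polyadenylation in vivo.  A terminal codon outside the expected set
warns but does not fail, since annotation slippage of a base or two is
common in deposited tables.

## RSCU

Codons are read in frame from base 1 of each annotated gene (no frame
search); a trailing partial codon — the incomplete-stop remnant — is
dropped, and codons containing N are skipped and tallied.  RSCU for
codon j in synonymous family i of size n_i is X_ij·n_i/ΣX_ij, families
defined by NCBI translation table 2 with Leu as the 6-codon union.
Stop codons form their own family: they are excluded from RSCU but
included in the amino-acid frequency denominator, so stop usage can be
reported alongside residue frequencies (documented choice; excluding
them changes frequencies by < 0.2% at mitogenome scale).  Unobserved
codons in an observed family get RSCU 0; a family with zero total is
reported missing, not 0.

## p-distance and Ka/Ks

p-distances use pairwise deletion: columns with a gap or ambiguity in
either member of a pair are dropped for that pair only.  The partition
(all / positions 1+2 / position 3) is applied by alignment column index
mod 3 before comparison, and the reported mean is the mean of pairwise
distances over all unordered pairs (a pooled-site statistic would weight
pairs by comparable length; the mean-of-pairs convention is labelled in
the output).

Ka/Ks is Nei–Gojobori (1986) with equal pathway weighting, chosen as the
transparent reference algorithm for counting methods.  Synonymous site
fractions count, at each codon position, the fraction of the three
possible point mutations that preserve the amino acid; mutations
creating a stop codon count as nonsynonymous.  For codons differing at
k positions, all k! single-step pathways are averaged with equal weight;
pathways passing through a stop codon are discarded unless every pathway
does.  Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 and reported missing with
a reason.  Uncorrected pS/pN are exposed alongside.  Codons containing
gaps or N in either sequence are removed pairwise; a terminal stop is
trimmed; an internal stop raises an error, as it indicates an alignment
frame problem rather than data noise.  Ka/Ks is reported missing when
Ks = 0; gene averages run over pairs with a defined ratio and count the
undefined ones.

Note that with ≤ 2 codons the method degenerates (pS easily exceeds 3/4);
it is meant for gene-length comparisons.

## tRNA cloverleaf analysis

Structures are consumed as dot-bracket strings, never predicted.  The
parser groups base pairs into helices (stacked runs, merging across
small internal bulges), requires 3 or 4 helices, takes the enclosing
helix as the acceptor (AA) stem and assigns the inner helices 5'→3' as
DHU, AC, TΨU; with 3 helices the structure is DHU-less (the
tRNA-Ser(GCT) case) and the first inner helix is the AC arm, validated
against the anticodon position when provided.  Stems plus loops
partition every sequence position exactly once, which is asserted as an
invariant.

The canonical 25-site map (8 AA + 5 DHU + 6 AC + 6 TΨU pairs) anchors
each stem's outermost pair at 1–87 (AA), 12–32 (DHU), 38–50 (AC) and
61–77 (TΨU) and interpolates inward with uniform offset.  The published
anchor pairs 1–87, 2–86, 8–80, 12–32, 40–48 and 64–74 all fall on this
grid; the remaining DHU anchor (15–30) implies a non-uniform offset
whose full map is not published, so the uniform interpolation is a
documented convention of this package, not a community standard.
Structures with shorter stems simply lack the innermost sites and drop
out of those denominators.

Pair classification treats T and U as equivalent: {A,T}/{G,C} are
Watson–Crick, {G,T} is the G-U wobble, anything else a mismatch labelled
by its alphabetically ordered bases.  Wobble percentages use the pairs
actually present as denominator.  The strand comparison is a two-sided
Mann–Whitney U on per-tRNA wobble percentages (H group vs L group),
delegated to scipy: exact p for small tie-free samples, normal
approximation with tie correction otherwise.

## Control-region annotation

Motif search is bounded-edit semi-global alignment with unit costs and a
lexicographic objective (total edits, then indel count), ties resolved
leftmost.  The best hit is the minimum-distance alignment; it is
rejected (no-hit) if its substitution count or indel count exceeds the
motif's budget.  Default budgets are 9 substitutions — the maximum
divergence load observed across the family for the CSB motifs — and 2
indels, overridable per motif in the library file.  With budgets (0,0)
the scan reduces exactly to substring search, which is asserted against
a naive-search oracle.

Divergence masks serialize an alignment in plain text: `*` identity,
uppercase query base = substitution, lowercase = insertion in the query,
`-` = deletion from the reference; applying the mask's edits to the
reference reconstructs the query exactly (tested invariant).  This is a
bit-exact replacement for bold/underline typography in print.

The shipped motif library splits the concatenated central-block
reference into CSB-F (23 nt), CSB-E (15 nt ending in the GTGGG box) and
CSB-D (24 nt), and the conserved-block reference into CSB-1 (24 nt),
CSB-2 (20 nt) and CSB-3 (23 nt).  The exact split points are not
published; the library records this package's split and is editable.
ETAS detection is deliberately excluded (not alignable in this family),
as is secondary-structure folding of the CSBs — the annotation exposes
motif sequences so an external folder can be applied.

Palindrome detection is exact matching of TACAT/ATGTA (each the reverse
complement of the other); T-homopolymers are maximal runs ≥ 5 (family
range 5–12); tandem repeats are exhaustively scanned for exact units of
2–20 bp with ≥ 3 copies, excluding units that are themselves periodic,
so homopolymers are not double-reported.

## Synthetic-data generator

The generator's defaults are the study conditions of the worked
example: the 38-feature canonical layout with its printed coordinates
(16,542 bp), whole-genome base probabilities A 0.275 / C 0.302 /
T 0.254 / G 0.169, the published start/stop pattern per PCG, tRNA sets
of 14 H + 8 L genes with per-stem wobble probabilities 0.03 (H) vs 0.13
(L), stem-length windows AA 6–8 / DHU 3–5 / AC 5–6 / TΨU 4–6 bp, and an
840 bp control region with the six CSBs, the 3'-terminal sequence,
palindrome copies near the 5' end and a T-run (default 8, range 5–12)
between CSB-D and CSB-1.  One seeded NumPy generator drives everything;
the seed fully determines the output.

Deliberate simplifications, and what passing tests therefore do and do
not show:

- PCG bodies are i.i.d. sense codons weighted by base-probability
  products — no amino-acid conservation, codon bias or rate variation.
  Tests on this data validate counting and bookkeeping, not biological
  realism of usage patterns.
- In overlap regions, features are written in genome order and the
  downstream feature's bases win; the truth report flags start/stop
  codons whose bases were overwritten, and codon-classification checks
  are restricted to intact genes.  Excluding stop codons from the codon
  sampler also leaves a small residual skew (≈ 0.03) even under
  symmetric base probabilities, so symmetry tests allow that margin.
- tRNA structures are clean cloverleaves without linker nucleotides or
  bulges; mismatch pairs are only planted when requested.  The
  multi-species mode (`n_species`) pools one structure per species per
  tRNA, matching the family-panel tallies in which each tRNA aggregates
  a few hundred base pairs — the regime in which the 3% vs 13% strand
  contrast is detected at p < 0.01 in essentially every replicate.
- Control-region filler is scrubbed of accidental palindromes, T-runs
  and tandem repeats (including across segment junctions), and the
  bases flanking each planted motif are forced to differ from the motif
  reference's terminal bases, so recorded ground truth is exact.  Edit
  placements are redrawn until the planted counts are also the
  minimal-alignment decomposition; with substitution-only plantings the
  annotator then recovers positions and counts exactly.  Planted
  indels adjacent to repetitive motif ends can still be re-expressed by
  the scanner's tie-break as equal-cost substitutions, so indel
  plantings guarantee recovery of the span (± 2 bp) at no more than the
  planted cost, not the exact decomposition.
- A 9-substitution load — the family's observed maximum — is only
  identifiable against a reference long enough that random windows
  cannot match as well; it is exercised on the 62 nt concatenated
  central block, while the 15 nt CSB-E fragment carries smaller loads.

## Problem sizes and tolerances

Statistical tests use sizes at which their targets are sharp: binomial
checks run at ≥ 500 pairs (3 standard errors), the neutral Ka/Ks check
averages 10 replicates of 500-codon pairs (tolerance 3 s.e. of the mean,
per-replicate s.d. ≈ 0.25 measured on that design), and the
strand-contrast power check runs 200 replicates of the 37-species panel.
Oracle comparisons (Nei–Gojobori enumeration, substring search, edlib
edit distance) are exact to 1e-12 or bitwise.
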