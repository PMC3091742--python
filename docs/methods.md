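# Methods

This note documents the models and procedures mitocomp implements, the
defaults it ships, and what its synthetic benchmarks do and do not show.

## Coordinates and genome representation

Genomes are held as the J-strand (majority-strand) sequence plus an ordered
feature table. Coordinates are 0-based half-open internally; GenBank's
1-based inclusive convention is converted at I/O. A feature crossing the
origin of a circular molecule is stored contiguously with
`end > genome length`, and all arithmetic is modulo the length — this keeps
overlap/spacer math free of special cases. N-strand features are read as
the reverse complement of their J-strand slice. The gene vocabulary is the
canonical metazoan set (13 protein genes, 2 rRNAs, 22 tRNA isoacceptors
with the L1=CUN / L2=UUR / S1=AGN / S2=UCN split) plus the control region;
duplicated genes take numeric suffixes, and unmappable labels are retained
verbatim and reported rather than dropped, since public records of these
genomes are frequently mis-annotated.

The rRNA boundary rule reflects how mite rRNAs are delimited in practice:
each rRNA is reset to abut its flanking tRNAs exactly (its 5'/3' ends are
the first nucleotides downstream/upstream of the neighbouring tRNA genes).

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed on J-strand
counts with ambiguous bases excluded from all denominators. Both the
signed value and the magnitude are reported: the sign convention varies in
the literature, and AT-rich mite genomes are commonly quoted by magnitude.
Skews are undefined (reported as None, never NaN) when a denominator is
zero. Per-codon-position A+T is computed over the concatenation of
in-frame CDS, dropping trailing partial codons.

The control-region scans are deliberately not thermodynamic folding.
T-stretch detection returns maximal runs of T per strand (an N-strand run
is a J-strand A run), each with the distance to the nearest annotated
feature; the default minimum run length is 4, the shortest run considered
a replication signal in these genomes. Stem-loop detection enumerates, for
every loop placement within configured bounds, the longest inverted repeat
whose outermost base pairs and whose internal mismatches stay within
budget; candidates are annotated for the conserved TATA / GA(A)T flanking
motifs. Complementarity (Watson–Crick, optionally G·U) is sufficient for
this hairpin screen; free energies are out of scope, so hairpin *counts*
depend on the structural bounds chosen and are not treated as fixed truths.

## Codon usage and RSCU

RSCU_i = n_i·k / Σ_{j∈family} n_j. The default family map reproduces the
arithmetic of the published mite codon-usage tables: leucine is split into
CUN (k=4) and UUR (k=2) families while serine is kept as a single
eight-codon AGN+UCN family (under the invertebrate mitochondrial code all
eight are serine), and AUA/AUG and UGA/UGG form two-codon Met and Trp
families. A strict per-amino-acid map is available as an alternative.
Stop codons are counted separately and excluded from the sense total N;
trailing incomplete codons and ambiguous codons are dropped and tallied.

Display rounding is exact-fraction round-half-up (via `Decimal`): the
published tables round ties upward (e.g. 4·51/96 = 2.125 printed as 2.13),
which binary-float half-even rounding would misreproduce. The shipped copy
of the published count table contains four RSCU cells that are one unit in
the printed last digit away from any value computable from the printed
counts under any rounding rule; the regression tests pin every other cell
exactly and those four to within one printed ULP.

## Gene order

A gene order is a circular signed permutation, canonicalised by rotating
cox1 to the front on '+' (reflecting and complementing first if needed), so
rotation and whole-molecule strand relabelling never affect comparisons.
A boundary is a circular adjacency; (X+,Y+) and (Y−,X−) are the same
boundary. With tRNAs and the control region included, 37 genes + CR give
38 boundaries — the element count under which published conserved-boundary
figures for these genomes are expressed. Genes absent from either genome
are excised from both before comparison (adjacency closure), and the
excisions are reported. Rearrangement labels per gene: `same_position`
when both neighbours (with relative orientation) match the reference,
`translocated_and_inverted` when the gene's orientation relative to the
shared cox1 anchor differs from the reference, `translocated` otherwise.
Minimal rearrangement distances (breakpoint/DCJ optimisation) are out of
scope.

Junction accounting walks consecutive features in J-strand coordinates,
reporting the signed gap at each junction (negative = overlap). The totals
obey Σ spacers + Σ lengths − Σ overlaps = genome length on any circular
record; overlaps between non-adjacent features are flagged as annotation
inconsistencies rather than silently tolerated.

## Truncated tRNA search

Mite mitochondrial tRNAs are too degenerate for cloverleaf-model scanners,
but their anticodon stem-loop is well conserved. The search therefore
anchors on every 7-nt window whose positions 3–5 spell an expected
isoacceptor anticodon (8-nt loops allowed for trnI only), requires a 5-bp
anticodon stem within a 1-mismatch budget, then extends outward to a 7-bp
acceptor stem within a 3-mismatch budget and 40–75 nt length bounds
(G·U counts as a pair throughout). The inter-stem regions are classified
as arms when they contain ≥2 contiguous pairs closing a ≥3-nt loop —
anything less is a replacement loop, matching the convention that 1-bp
"arms" are not credible. Structure classes follow from the arm flags:
cloverleaf, TV-replacement (T-arm replaced), D-replacement, or armless
candidate. Candidates are scored by (fewest stem mismatches, most arms,
shortest gene, leftmost start); per anticodon anchor a short list of
geometries is kept. Arm inference runs only on a shortlist pre-ranked by
mismatches and length — arms are the second tie-break criterion, so the
shortlist retains the best candidates at a fraction of the cost.

Isoacceptor assignment is homology-based, as in manual re-annotation:
each candidate is globally aligned (match 1, mismatch −1, gap open −2,
extend −1) against per-isoacceptor references from related taxa;
assignment is greedy by alignment identity with one-to-one locus
occupancy (≥50% span overlap on the same strand counts as the same locus)
and a default minimum identity of 0.60. Overlap with adjacent genes never
disqualifies a candidate — the most truncated mite tRNAs overlap their
neighbours by 10–14 nt. The anticodon table covers the standard
invertebrate-mitochondrial wobble set, with both observed variants for
trnK (UUU/CUU) and trnS1 (UCU/GCU).

## Substitution rates

Distances: p-distance with pairwise deletion of gap/ambiguity columns;
Jukes–Cantor d = −(3/4)·ln(1 − 4p/3); gamma-rate generalisation
d = (3α/4)((1 − 4p/3)^(−1/α) − 1). The gamma shape α is a user input —
model selection is out of scope. p ≥ 0.75 is flagged as saturated rather
than propagated.

Ka/Ks is classical Nei–Gojobori (1986): per-codon synonymous site
fractions by enumerating the three alternatives at each position
(mutations to stops excluded from the denominator), observed differences
resolved by averaging over all minimal substitution pathways with equal
weights (pathways through stop codons discarded when a stop-free pathway
exists), JC correction applied to ps = Sd/S and pn = Nd/N. Published mite
analyses used MEGA's "Kumar method", a variant of this family whose exact
modifications are not documented; the method name is recorded in the
output metadata so downstream users know which estimator produced the
numbers. Codon alignments are inputs, not computed here; a back-translation
utility maps protein alignments onto CDS. Bootstrap standard errors
resample codons (for Ka/Ks) or sites (for distances) with a seeded
generator, 500 replicates by default; replicates where the estimator is
undefined are dropped, and more than 50% undefined is an error, not a
number.

## Synthetic genomes

The generator's defaults emulate the study conditions for a mite
mitogenome: 13,077 bp, 37 genes + CR in the arthropod ground-pattern
order, 85% A+T target with signed skews (AT −0.071, GC +0.03), protein
gene lengths summing to 10,196 bp (with truncated T/TA stops where lengths
are not codon multiples), rRNAs of 989 and 648 bp, a 57 bp A+T-only
control region carrying a 4-bp J-strand T-stretch (6 nt from the CR
start), a 6-bp N-strand stretch (17 nt from its end) and an A/T hairpin,
22 tRNAs of 44–62 nt (mean 54.1) in the published class census
(3 cloverleaf, 6 D-replacement, 13 TV-replacement), and 11 overlapping
junctions totalling 55 bp with a 14 bp maximum. Background sequence is
i.i.d. from the target composition; N-strand genes are sampled from the
complemented composition so the molecule-level strand asymmetry is
realized. Codon sampling uses a fixed-point calibration so that excluding
the AT-rich stop codons does not depress the realized A+T. tRNAs are built
stem-first (perfectly paired stems, non-pairing poly-A replacement loops),
guaranteeing the declared structure class is detectable; large junction
overlaps are placed where the overwritten neighbour is unconstrained
(rRNA or control region), and tRNA/tRNA overlaps are capped at 3 bp so the
upstream tRNA stays within its acceptor-stem mismatch budget.

What the generator does **not** emulate: codon-usage bias beyond base
composition, rRNA secondary structure, repeat elements, realistic
evolutionary divergence along a tree, or indels. Passing recovery tests on
these genomes shows the algorithms are correct under the stated
statistical conditions — not that they will match hand annotation on any
real record.

`permute_order` applies seeded block translocations and inversions
(never touching the cox1 anchor, which defines the orientation frame) and
emits truth labels computed directly from the boundary definition.
`mutate_cds` inverts the JC correction to per-site substitution
probabilities and applies synonymous/nonsynonymous changes per codon
position with probabilities fs·ps and fn·pn (never creating stops);
NG86 re-estimation recovers the targets to within ~15% at 300 codons.

## Problem sizes and numerical choices

The shipped test suite exercises: the full published codon table; a
brute-force pathway-enumeration oracle against NG86 on 1000+ random codon
pairs of up to 30 codons; inverted-repeat scans against an O(n³)
enumerator on sequences up to 60 nt; 50 simulated genomes (1100 planted
tRNAs) for recovery at references diverged by 10%; 40 seeded random
rearrangements for label recovery; and 20 seeds × 300 codons for Ka/Ks
recovery. These sizes were chosen to make the statistical checks stable
while keeping the whole suite fast enough to run routinely.

Ties everywhere are broken deterministically (scores, then position);
all stochastic components take explicit seeds and are reproducible
byte-for-byte.

## Known limitations

- The accession-reproduction checks need the GenBank flat file locally;
  the package does not download data.
- The conserved-boundary count depends on the documented matching rule
  (tRNAs and CR included, orientation-aware adjacencies); other rules give
  other counts.
- Stem-loop candidate counts are parameter-dependent by design.
- The Ka/Ks estimator is the classical NG86; it will differ from MEGA's
  modified variants in the second decimal for diverged pairs.
- Armless tRNA candidates are reported but biological validation of such
  genes is an open question; the classifier states its thresholds rather
  than claiming truth.
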