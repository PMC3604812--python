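# Methods

This note documents the models and procedures implemented in brasskit,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic-data validation does and
does not demonstrate.

## The synthetic genome generator

The generator (`brasskit.simulate`) emulates the data situation of a
karyotype-guided chromosome build in a crucifer-like genome. It is the
package's source of ground truth: every emitted gene, scaffold and
satellite array has exactly one ground-truth record, and a fixed
`SimulationConfig` plus seed yields byte-identical output files.

**Ancestral genome and karyotype.** The ancestral gene order consists
of `n_blocks` = 24 blocks (single letters A–X) with 30–60 genes each
(uniform per block). Blocks are shuffled, partitioned contiguously
over `n_chromosomes` = 7 chromosomes (at least two blocks per
chromosome whenever the counts allow, so the centromere can sit at an
interior block junction), and each block receives an independent
random sign; a '−' block contributes its genes in descending ancestral
order on '−' strands. The centromere index is drawn uniformly among
interior block junctions.

**Fragmentation.** Gene bodies are i.i.d. random sequence of 180 bp
separated by 60 bp intergenic spacers; between 10% of gene pairs a
100 bp N run is inserted. Chromosomes are cut at inter-gene midpoints
into the requested total number of scaffolds (default 40), with a
floor of 5 genes per scaffold — draft assemblies do not produce
arbitrarily tiny gene-bearing scaffolds, and a 1–2 gene fragment
carries no usable orientation signal. Each scaffold is independently
reverse complemented with probability 0.5 (flip recorded), and
scaffold names are shuffled so downstream code cannot exploit emission
order. Intergenic and gene sequence is uniform over A/C/G/T, which
avoids accidental periodicity that could confuse satellite detection.

**Satellites.** Each chromosome's breakpoint nearest the centromere is
treated as the centromeric junction; the two flanking scaffolds
receive a planted tandem array at the junction-facing terminus (a
single-scaffold chromosome gets one array at the terminus nearest the
centromere). The monomer (default period 177 bp) is drawn with
per-position AT probability 0.7; each of the 30–60 copies is then
mutated at 1% per base, so arrays are detectable but not literal
repeats.

**Ortholog identities.** Pair identities are drawn from a
two-component truncated-normal mixture on [0, 1] with modes 0.85
(close relative) and 0.35 (distant outgroup), standard deviations 0.08
and 0.10, and high-mode weight 0.8 — the regime in which roughly 80%
of genes have high-homology orthologs. Identities are *drawn*, not
evolved; there is no substitution model, no alignment, and therefore
no length- or composition-dependence of identity. Note that the
truncation shifts component *means* slightly off the modes; tests
compare sample means against the truncated-normal expectation, not
the mode.

**Codon-biased genes.** Given a tRNA pool, "adapted" genes draw each
codon proportionally to its relative adaptiveness *w* within the
synonymous family, and "uniform" genes draw uniformly; the per-gene
flag is recorded. Because wobble pairing gives nonzero *w* to codons
without a dedicated tRNA, adapted genes concentrate on — but are not
confined to — directly decoded codons. The default synthetic pool puts
Watson–Crick anticodons at uneven copy numbers (0–8) with at least one
decoder per amino acid.

## Assembly metrics

N50/L50 nomenclature is used inconsistently in the assembly
literature; this package fixes **N50 = the smallest count of scaffolds
whose summed length reaches half the assembly span** and **L50 = the
length of the scaffold at that point**, and uses that convention
everywhere. Contigs are maximal non-N runs after bridging N runs
shorter than `min_gap_run` (default 10, a common assembler
convention; exposed as a flag). Table percentages use round-half-even
at 2 decimals (non-gap) and 1 decimal (gap fraction) so table cells
are reproducible.

## Satellite detection

Period estimation is base-match autocorrelation: for candidate period
*p* in `[min_period, max_period]` (defaults 50–500, bracketing the
~177 bp centromeric satellite class), score(*p*) is the fraction of
window positions *i* with base(*i*) = base(*i*+*p*); 'N' never counts
as a match, so gap runs cannot fake periodicity. A period is called
when the best score reaches `match_threshold` (default 0.8), and among
candidates within 0.01 of the best the smallest period wins, which
suppresses harmonics (2*p*, 3*p*, …). Windows of 3× the maximum period
with 50% overlap are scanned; same-period windows (±2 bp) are merged,
boundaries are refined outward in period-sized steps then single
bases, and the consensus is the per-column majority over phase-aligned
full copies. A suffix-tree tandem-repeat finder would be more general;
autocorrelation was chosen because it is simple, exactly testable, and
adequate for high-copy satellites. Terminal classification uses a 10%
margin of scaffold length at either end, nearer-terminus winning when
both qualify (ties go left).

## Block painting

The gene track of a scaffold is segmented into maximal runs of one
block label, tolerating up to `max_interleave` = 2 consecutive
foreign-label genes inside a run (absorbed and logged — single-gene
transpositions and mismappings should not break a block), and
discarding runs with fewer than `min_run` = 3 same-label genes.
Orientation is the sign of Kendall's τ between scaffold order and
ancestral rank, reported only when |τ| ≥ 0.5 ('?' otherwise); a rank
statistic is robust to a few mismapped genes where a simple
first-vs-last comparison is not. Gene→block membership is an
authoritative input; genes mapping ambiguously to two blocks are not
modelled.

## Karyotype-guided assembly

Scaffolds are matched largest-first (by painted gene count): a
scaffold's block-label sequence must occur contiguously in one
chromosome's block order, forward or reversed with signs flipped, and
the orientation with the higher sign agreement wins. Fragmentation
routinely cuts inside blocks, so one block may be shared by several
scaffolds; the matcher therefore claims only the *interior* block
positions of a multi-block scaffold exclusively, while boundary blocks
may be shared. Within a block, scaffolds are ordered by the mean
ancestral index of their segment, ascending when the karyotype carries
the block '+' and descending when '−'. Satellite evidence outranks
sign agreement: a satellite-bearing terminus must face the centromere
(scaffolds spanning the centromere are unconstrained), and when the
override flips the sign-preferred orientation an
`orientation_conflict` is recorded. Scaffolds are never split;
unmatched or conflicting scaffolds go to the unplaced bin and the
discrepancy report (missing blocks, split blocks, order conflicts,
residual sign disagreements). Pseudomolecules join scaffolds with
100 N (AGP v2.0 gap type U, linkage no); ideograms use a fixed
letter-keyed 24-color palette so figures are reproducible.

## Homology

A protein pair's overall identity tiles its alignment fragments on the
query axis in descending matched-position order; a later fragment
contributes only uncovered query columns, with its matches pro-rated
over the surviving columns, and identity = surviving matches / tiled
columns. The greedy keep-the-stronger rule and the query-column
denominator (rather than alignment columns including subject-only
gaps) are explicit conventions of this implementation; both are
deterministic and input-order invariant. Best hits maximize identity,
with ties broken by larger tiled column count then lexicographically
smaller subject id. Mode detection uses a Gaussian KDE (Silverman's
bandwidth by default, overridable) on a 512-point grid over [0, 1];
modes are interior local maxima with density ≥ 10% of the global
maximum, and at least 50 values are required. The crossing point of an
ingroup/outgroup density pair is the sign change of the density
difference between the two principal modes nearest their midpoint,
linearly interpolated within the grid cell. Classification bins are
half-open: identity < 0.30 → no homolog, [0.30, 0.60) → low, ≥ 0.60 →
high.

## Gene families

Two same-family genes form a tandem pair when they are consecutive
family members on a scaffold and their gene-order indices differ by
strictly less than 20 (exactly 20 apart is *not* tandem; both the
threshold and an all-pairs variant are flags). A homology cluster of
size ≥ 2 is lineage-specific to a species when all members belong to
it. Copy-number enrichment between two species uses Fisher's exact
test on the family-vs-rest 2×2 table with Benjamini–Hochberg
adjustment across families — a deliberate, documented choice, since
enrichment analyses of this kind often leave the test unnamed.

## tAI

Absolute adaptiveness W of a codon sums (1 − s)·tGCN over recognizing
anticodons, with the standard selective penalties: Watson–Crick 0,
G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68, and 0.89 for the
lysidine-modified CAU anticodon reading AUA. Wobble recognition is
restricted to anticodons whose own Watson–Crick codon encodes the same
amino acid, so decoding never crosses synonymous families (the
lysidine rule is the sole exception); this keeps Met and Trp decoded
only by their cognate tRNAs. Relative adaptiveness w = W / max W, with
w = 0 codons replaced by the geometric mean of the nonzero w so an
undecodable codon does not zero out a gene. A gene's tAI is the
geometric mean of its codons' w, excluding a single terminal stop
(internal stops are an error). The cross-species family comparison is
a two-sided Wilcoxon rank-sum test — exact by enumeration for combined
n ≤ 20, normal approximation with continuity correction otherwise —
reported with the direction of the median difference, so a one-sided
claim can be recovered without silently encoding sidedness. The
significance threshold used in reports is adjusted p < 0.05.

## Validation scope and limitations

The test suite and `scripts/acceptance.py` validate the pipeline by
parameter recovery on generator output: simulated scaffolds are
re-placed with 100% accuracy without noise and ≈99–100% with 5%
mislabeled genes (20 seeds, 30–60 scaffolds each); planted satellite
periods in 150–200 bp are recovered within ±1 bp in ≥95% of arrays;
mixture modes are recovered within ±0.02 and the density crossing
falls strictly between them. Problem sizes (≈0.4 Mb genomes, 10,000
identity pairs, 60–100 coding genes per run) were chosen so the whole
suite completes in well under a minute per module while keeping every
statistical check comfortably powered.

These results show correctness of the algorithms under the generator's
assumptions, not performance on real assemblies: the generator has no
sequence evolution, no repeat families other than the planted
satellites, no mapping ambiguity, uniform base composition, and
scaffold fragmentation at clean inter-gene boundaries. Real data adds
mismapped and tandemly duplicated reference genes, satellite
higher-order repeat structure, and segmental duplications, all of
which can only degrade — not bias — the discrete matching rules, but
whose magnitude the synthetic tests cannot quantify.
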