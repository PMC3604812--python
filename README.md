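# brasskit

Comparative-genomics toolkit for small plant genomes of the crucifer
(Brassicaceae) type, built around the workflow used to turn a
scaffold-level draft assembly into chromosome-scale pseudomolecules
when a cytogenetic karyotype — but no genetic map — is available.

Crucifer genomes can be described as rearrangements of 24 conserved
ancestral genomic blocks, labelled A–X, each defined by a syntenic set
of reference genes. Given (i) where those reference genes land on the
scaffolds of a new assembly, (ii) the species' experimentally derived
karyotype as an ordered list of signed blocks per chromosome, and
(iii) centromeric satellite arrays marking the centromere-facing ends
of scaffolds, the scaffolds can be ordered and oriented into full
chromosomes without breaking any scaffold — genuine lineage-specific
rearrangements surface as reported discrepancies instead.

The package implements that pipeline plus the bespoke statistics that
accompany this kind of genome study:

- **`simulate`** — synthetic genomes with exported ground truth: an
  ancestral block gene order rearranged into an *n*-chromosome
  karyotype, fragmented into flipped scaffolds with N-gap runs,
  AT-rich tandem satellite arrays planted at pericentromeric scaffold
  termini, bimodal ortholog-identity draws, and codon-usage-biased
  gene sets under a tRNA pool. Every downstream module is validated by
  parameter recovery against this generator.
- **`metrics`** — assembly contiguity: contig splitting at N runs,
  N50/L50 (N50 = minimal number of scaffolds covering half the span,
  L50 = length of the scaffold at that point), cumulative size tables,
  gap fraction, alignment discrepancy rate.
- **`satellite`** — tandem-repeat detection by base-match
  autocorrelation: for candidate period *p* the score is the fraction
  of positions *i* with base(*i*) = base(*i*+*p*); harmonics are
  suppressed by preferring the smallest near-optimal period. Arrays
  are classified as scaffold-terminal or internal for orientation
  evidence.
- **`blockpaint`** — segmenting each scaffold's reference-gene track
  into maximal ancestral-block runs; segment orientation is the sign
  of Kendall's τ between scaffold order and ancestral gene rank
  (gated at |τ| ≥ 0.5).
- **`karyotype`** — largest-first matching of painted scaffolds onto
  the karyotype template, satellite-aware orientation, AGP v2.0 and
  chromosome FASTA emission, discrepancy reports, SVG ideograms
  ("digital karyotypes").
- **`homology`** — overall identity of a protein pair by greedy tiling
  of alignment fragments on the query axis (identity = surviving
  matches / tiled columns), per-query best hits, mode detection in the
  smoothed identity density, and the crossing point of an
  ingroup/outgroup density pair as a principled high-homology cutoff.
- **`families`** — tandem-duplication calls (two same-family genes
  fewer than 20 gene positions apart), lineage-specific homology
  clusters, and per-family copy-number enrichment (Fisher's exact
  test, Benjamini–Hochberg).
- **`tai`** — the tRNA adaptation index. For codon *c*,
  *W<sub>c</sub>* = Σ<sub>j</sub> (1 − *s<sub>cj</sub>*)·tGCN<sub>j</sub>
  over recognizing anticodons *j*, *w<sub>c</sub>* = *W<sub>c</sub>* / max *W*,
  and a gene's tAI is the geometric mean of its codons' *w*. Families
  are compared across species with a Wilcoxon rank-sum test (exact
  null for combined *n* ≤ 20).

## Worked example

```python
from brasskit.simulate import SimulationConfig, simulate_all
from brasskit import validation, metrics, karyotype as kt

cfg = SimulationConfig(seed=1, n_scaffolds=40)
genome = simulate_all(cfg, n_pairs=10000, n_cds=100)
stats = metrics.contiguity_stats(genome.scaffolds)
print(f"scaffolds: {len(genome.scaffolds)}  span: {stats.scaffold_span:,} bp  "
      f"N50/L50: {stats.n50_count}/{stats.l50_length:,} bp  gap: {stats.gap_pct}%")

plan, disc, painted = validation.assemble_simulated(genome)
placed = sum(len(v) for v in plan.chromosomes.values())
print(f"placed {placed}/{len(genome.scaffolds)} scaffolds on "
      f"{len(plan.chromosomes)} chromosomes; {len(disc)} discrepancies")
print(f"recovery vs ground truth: {validation.scaffold_recovery_score(genome, plan):.3f}")
```

prints

```
scaffolds: 40  span: 380,074 bp  N50/L50: 10/13,484 bp  gap: 2.7%
placed 40/40 scaffolds on 7 chromosomes; 0 discrepancies
recovery vs ground truth: 1.000
```

i.e. the simulated 7-chromosome genome was fragmented into 40
scaffolds (2.7% of the span is N-gap), and painting + satellite
detection + karyotype matching put every scaffold back on its true
chromosome in the true orientation with no conflicts.

The same pipeline is available from the shell:

```sh
brasskit simulate --out sim --seed 1
brasskit stats --fasta sim/scaffolds.fasta
brasskit assemble --karyotype sim/karyotype.json --placements sim/placements.tsv \
    --blocks sim/blocks.tsv --fasta sim/scaffolds.fasta --out asm
```

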