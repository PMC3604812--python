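"""Synthetic crucifer-style genomes with exported ground truth.

The generator emulates the data situation of a karyotype-guided
chromosome build: an ancestral gene order organized into conserved
blocks (labelled A, B, ... as in the 24-block crucifer system) is
rearranged into a small number of chromosomes, fragmented into
scaffolds with N-gap runs and random flips, and AT-rich tandem
satellite arrays are planted at the scaffold termini flanking each
centromere.  Ortholog identities are drawn from a two-component
truncated-normal mixture (a close-relative mode and a distant-outgroup
mode), and coding sequences are drawn either uniformly over synonymous
codons or proportionally to tRNA adaptiveness.

Everything is driven by one integer seed and every emitted entity has
exactly one ground-truth record, so downstream modules can be tested
by parameter recovery.  Identities are drawn, not evolved: there is no
substitution/indel model along a phylogeny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .blockpaint import BLOCK_ALPHABET, GenePlacement
from .tai import GENETIC_CODE, SENSE_CODONS, reverse_complement, wc_anticodon

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic genome."""

    seed: int = 0
    n_blocks: int = 24
    genes_per_block: tuple[int, int] = (30, 60)
    n_chromosomes: int = 7
    n_scaffolds: int = 40
    satellite_period: int = 177
    satellite_copies: tuple[int, int] = (30, 60)
    satellite_at_fraction: float = 0.7
    satellite_mutation_rate: float = 0.01
    identity_modes: tuple[float, float] = (0.85, 0.35)
    identity_sds: tuple[float, float] = (0.08, 0.10)
    mixture_weight: float = 0.8
    gap_run_length: int = 100
    gap_probability: float = 0.1
    intergenic_length: int = 60
    gene_length: int = 180
    cds_length_aa: int = 150
    min_genes_per_scaffold: int = 5  # fragmentation floor: no scaffold below this many genes

    def validate(self) -> None:
        if self.n_blocks > len(BLOCK_ALPHABET):
            raise ValueError("single-letter block labels exhausted (n_blocks > 26)")
        if self.n_blocks < self.n_chromosomes:
            raise ValueError("need at least one block per chromosome")
        if self.n_scaffolds < self.n_chromosomes:
            raise ValueError("need at least one scaffold per chromosome")
        if self.satellite_period < 2:
            raise ValueError("satellite period must be >= 2")
        for frac in (
            self.satellite_at_fraction,
            self.mixture_weight,
            *self.identity_modes,
            *self.identity_sds,
            self.gap_probability,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.genes_per_block[0] < 1 or self.genes_per_block[0] > self.genes_per_block[1]:
            raise ValueError("invalid genes_per_block range")


@dataclass(frozen=True)
class AncestralGene:
    gene: str
    block: str
    index: int


@dataclass
class Chromosome:
    name: str
    blocks: list[tuple[str, str]]  # (sign, label)
    centromere_after: int  # centromere between blocks[i] and blocks[i+1]


@dataclass
class KaryotypeDefinition:
    chromosomes: list[Chromosome]

    def to_json(self) -> dict:
        return {
            "chromosomes": [
                {
                    "name": c.name,
                    "blocks": [s + b for s, b in c.blocks],
                    "centromere_after": c.centromere_after,
                }
                for c in self.chromosomes
            ]
        }

    @classmethod
    def from_json(cls, obj: dict) -> "KaryotypeDefinition":
        return cls(
            [
                Chromosome(
                    c["name"],
                    [(b[0], b[1:]) for b in c["blocks"]],
                    int(c["centromere_after"]),
                )
                for c in obj["chromosomes"]
            ]
        )


@dataclass
class GroundTruth:
    gene_blocks: dict[str, tuple[str, int]]
    scaffold_truth: dict[str, dict]  # name -> {chromosome, rank, orientation}
    satellites: list[dict]  # {scaffold, start, end, period, copies}
    identity_classes: dict[str, int]
    codon_bias_flags: dict[str, str]


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    ancestral: list[AncestralGene]
    karyotype: KaryotypeDefinition
    chromosome_orders: dict[str, list[tuple[str, str]]]  # chrom -> [(gene, strand)]
    scaffolds: dict[str, str]
    placements: dict[str, list[GenePlacement]]
    truth: GroundTruth


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def simulate_ancestral_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> list[AncestralGene]:
    """Gene order of the ancestral genome: blocks A.. with per-block
    strictly increasing ancestral indices."""
    config.validate()
    genes: list[AncestralGene] = []
    gid = 0
    lo, hi = config.genes_per_block
    for b in range(config.n_blocks):
        label = BLOCK_ALPHABET[b]
        count = int(rng.integers(lo, hi + 1))
        for i in range(count):
            genes.append(AncestralGene(f"g{gid:05d}", label, i))
            gid += 1
    return genes


def simulate_karyotype(
    config: SimulationConfig,
    ancestral: Sequence[AncestralGene],
    rng: np.random.Generator,
) -> tuple[KaryotypeDefinition, dict[str, list[tuple[str, str]]]]:
    """Rearrange blocks into chromosomes with random order and signs.

    Each block lands on exactly one chromosome with a random sign; a
    block with sign '-' contributes its genes in descending ancestral
    order on '-' strands.  The centromere is placed between two
    adjacent blocks (interior position) on every chromosome with at
    least two blocks.
    """
    labels = sorted({g.block for g in ancestral})
    order = [labels[i] for i in rng.permutation(len(labels))]
    n = config.n_chromosomes
    # contiguous partition, each chromosome gets >=2 blocks when possible
    min_per = 2 if len(labels) >= 2 * n else 1
    sizes = np.full(n, min_per)
    extra = len(labels) - int(sizes.sum())
    for _ in range(extra):
        sizes[int(rng.integers(0, n))] += 1
    by_block = {}
    for g in ancestral:
        by_block.setdefault(g.block, []).append(g)
    chroms: list[Chromosome] = []
    orders: dict[str, list[tuple[str, str]]] = {}
    pos = 0
    for ci in range(n):
        chunk = order[pos : pos + int(sizes[ci])]
        pos += int(sizes[ci])
        signed = [("+" if rng.random() < 0.5 else "-", lab) for lab in chunk]
        cen = int(rng.integers(0, len(chunk) - 1)) if len(chunk) >= 2 else 0
        name = f"Chr{ci + 1}"
        chroms.append(Chromosome(name, signed, cen))
        gene_order: list[tuple[str, str]] = []
        for sign, lab in signed:
            block_genes = by_block[lab]
            if sign == "+":
                gene_order.extend((g.gene, "+") for g in block_genes)
            else:
                gene_order.extend((g.gene, "-") for g in reversed(block_genes))
        orders[name] = gene_order
    return KaryotypeDefinition(chroms), orders


def _satellite_array(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, int, int]:
    """One planted tandem array: (sequence, period, n_copies).

    The monomer is drawn with per-position AT probability equal to
    ``satellite_at_fraction``; each copy is then mutated independently
    at ``satellite_mutation_rate`` per base.
    """
    p = config.satellite_period
    at = rng.random(p) < config.satellite_at_fraction
    pick_at = rng.integers(0, 2, p)  # A or T
    pick_gc = rng.integers(0, 2, p)  # C or G
    monomer = np.where(at, np.where(pick_at == 0, ord("A"), ord("T")),
                       np.where(pick_gc == 0, ord("C"), ord("G"))).astype(np.uint8)
    copies = int(rng.integers(config.satellite_copies[0], config.satellite_copies[1] + 1))
    arr = np.tile(monomer, copies)
    mut = rng.random(arr.size) < config.satellite_mutation_rate
    arr[mut] = BASES[rng.integers(0, 4, int(mut.sum()))]
    return arr.tobytes().decode("ascii"), p, copies


def emit_scaffolds(
    config: SimulationConfig,
    karyotype: KaryotypeDefinition,
    chromosome_orders: Mapping[str, list[tuple[str, str]]],
    ancestral: Sequence[AncestralGene],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[GenePlacement]], GroundTruth]:
    """Fragment chromosomes into scaffolds and plant centromeric arrays.

    Chromosomes are cut at intergenic breakpoints into the requested
    total number of scaffolds; each scaffold is independently reverse
    complemented with probability 0.5 (recorded); the two scaffold
    termini flanking the breakpoint nearest each centromere receive a
    planted satellite array; N-gap runs are inserted between genes at
    the configured rate.  All coordinates are 0-based half-open.
    """
    config.validate()
    gene_blocks = {g.gene: (g.block, g.index) for g in ancestral}
    block_of = {g.gene: g.block for g in ancestral}

    # scaffold counts per chromosome (>=1 each)
    chrom_names = [c.name for c in karyotype.chromosomes]
    counts = {name: 1 for name in chrom_names}
    weights = np.array([len(chromosome_orders[n]) for n in chrom_names], dtype=float)
    weights /= weights.sum()
    for _ in range(config.n_scaffolds - len(chrom_names)):
        counts[chrom_names[int(rng.choice(len(chrom_names), p=weights))]] += 1

    pieces: list[dict] = []  # unflipped scaffold pieces in chromosome order
    for chrom in karyotype.chromosomes:
        order = chromosome_orders[chrom.name]
        # build chromosome piecewise, remembering gene coords and block bounds
        seq_parts: list[str] = []
        coords: list[tuple[str, int, int, str]] = []
        pos = 0
        boundary_after_gene: list[int] = []  # chromosome coord of each inter-gene midpoint
        cen_after = chrom.centromere_after
        genes_before_cen = sum(
            len([g for g in ancestral if g.block == lab])
            for _, lab in chrom.blocks[: cen_after + 1]
        )
        cen_coord = None
        for gi, (gene, strand) in enumerate(order):
            inter = _rand_seq(rng, config.intergenic_length)
            if gi > 0 and rng.random() < config.gap_probability:
                half = config.intergenic_length // 2
                inter = inter[:half] + "N" * config.gap_run_length + inter[half:]
            seq_parts.append(inter)
            pos += len(inter)
            if gi > 0:
                boundary_after_gene.append(pos - len(inter) // 2)
            if gi == genes_before_cen:
                cen_coord = pos - len(inter) // 2
            gseq = _rand_seq(rng, config.gene_length)
            seq_parts.append(gseq)
            coords.append((gene, pos, pos + config.gene_length, strand))
            pos += config.gene_length
        seq_parts.append(_rand_seq(rng, config.intergenic_length))
        chrom_seq = "".join(seq_parts)
        if cen_coord is None:
            cen_coord = len(chrom_seq) // 2

        # pick cut sites at inter-gene boundaries, keeping every piece at
        # least min_genes_per_scaffold genes long
        n_cuts = counts[chrom.name] - 1
        min_g = max(1, config.min_genes_per_scaffold)
        accepted_gi: list[int] = []  # boundary i sits before gene i+1
        for i in rng.permutation(len(boundary_after_gene)):
            gi = int(i) + 1  # genes before this boundary
            if len(accepted_gi) >= n_cuts:
                break
            if gi < min_g or len(order) - gi < min_g:
                continue
            if all(abs(gi - a) >= min_g for a in accepted_gi):
                accepted_gi.append(gi)
        cut_sites = sorted(boundary_after_gene[g - 1] for g in accepted_gi)
        bounds = [0] + cut_sites + [len(chrom_seq)]
        # centromeric junction: boundary (incl. chromosome ends) nearest centromere
        junctions = bounds[1:-1]
        chrom_pieces = []
        for rank in range(len(bounds) - 1):
            lo, hi = bounds[rank], bounds[rank + 1]
            piece_genes = [
                (g, s - lo, e - lo, st) for g, s, e, st in coords if s >= lo and e <= hi
            ]
            chrom_pieces.append(
                {
                    "chromosome": chrom.name,
                    "rank": rank,
                    "seq": chrom_seq[lo:hi],
                    "genes": piece_genes,
                    "sat_side": None,
                }
            )
        if junctions:
            j = min(range(len(junctions)), key=lambda k: abs(junctions[k] - cen_coord))
            chrom_pieces[j]["sat_side"] = "right"
            chrom_pieces[j + 1]["sat_side"] = "left"
        else:
            lone = chrom_pieces[0]
            lone["sat_side"] = (
                "left" if cen_coord < len(lone["seq"]) / 2 else "right"
            )
        pieces.extend(chrom_pieces)

    # plant satellite arrays at centromere-facing termini
    sat_truth_pre: list[tuple[int, int, int, int, int]] = []  # piece idx, start, end, period, copies
    for pi, piece in enumerate(pieces):
        if piece["sat_side"] is None:
            continue
        arr, period, copies = _satellite_array(config, rng)
        if piece["sat_side"] == "right":
            start = len(piece["seq"])
            piece["seq"] = piece["seq"] + arr
            sat_truth_pre.append((pi, start, start + len(arr), period, copies))
        else:
            piece["seq"] = arr + piece["seq"]
            piece["genes"] = [
                (g, s + len(arr), e + len(arr), st) for g, s, e, st in piece["genes"]
            ]
            sat_truth_pre.append((pi, 0, len(arr), period, copies))

    # name scaffolds in shuffled order, flip each with probability 0.5
    perm = rng.permutation(len(pieces))
    scaffolds: dict[str, str] = {}
    placements: dict[str, list[GenePlacement]] = {}
    scaffold_truth: dict[str, dict] = {}
    names = {}
    for out_i, pi in enumerate(perm):
        names[int(pi)] = f"scf{out_i + 1:03d}"
    flips = {int(pi): bool(rng.random() < 0.5) for pi in range(len(pieces))}
    for pi_raw in sorted(names):
        pi = int(pi_raw)
        piece = pieces[pi]
        name = names[pi]
        seq = piece["seq"]
        genes = piece["genes"]
        if flips[pi]:
            L = len(seq)
            seq = reverse_complement(seq)
            genes = [
                (g, L - e, L - s, "-" if st == "+" else "+") for g, s, e, st in genes
            ]
            genes.sort(key=lambda t: t[1])
        scaffolds[name] = seq
        placements[name] = [GenePlacement(g, s, e, st) for g, s, e, st in genes]
        scaffold_truth[name] = {
            "chromosome": piece["chromosome"],
            "rank": piece["rank"],
            "orientation": "-" if flips[pi] else "+",
        }
    satellites = []
    for pi, s, e, period, copies in sat_truth_pre:
        name = names[pi]
        L = len(pieces[pi]["seq"])
        if flips[pi]:
            s, e = L - e, L - s
        satellites.append(
            {"scaffold": name, "start": s, "end": e, "period": period, "copies": copies}
        )
    truth = GroundTruth(
        gene_blocks=gene_blocks,
        scaffold_truth=scaffold_truth,
        satellites=sorted(satellites, key=lambda d: (d["scaffold"], d["start"])),
        identity_classes={},
        codon_bias_flags={},
    )
    # order scaffolds by name for deterministic emission
    scaffolds = {k: scaffolds[k] for k in sorted(scaffolds)}
    placements = {k: placements[k] for k in sorted(placements)}
    return scaffolds, placements, truth


def simulate_ortholog_identities(
    config: SimulationConfig, n_pairs: int, rng: np.random.Generator
):
    """Draw pair identities from a two-component truncated-normal mixture.

    Component 0 is the high-identity (close relative) mode, component 1
    the low-identity (outgroup) mode; the true component of each pair
    is recorded.  Returns a DataFrame (pair, identity, component).
    """
    import pandas as pd

    m = config.identity_modes
    sd = config.identity_sds
    if m[0] == m[1]:
        raise ValueError("mixture modes must be distinct")
    if abs(m[0] - m[1]) < 2 * max(sd):
        import warnings

        warnings.warn("identity modes overlap heavily; classes will be confusable")
    comp = (rng.random(n_pairs) >= config.mixture_weight).astype(int)
    vals = np.empty(n_pairs)
    for k in (0, 1):
        idx = np.flatnonzero(comp == k)
        if idx.size:
            a, b = (0.0 - m[k]) / sd[k], (1.0 - m[k]) / sd[k]
            vals[idx] = stats.truncnorm.rvs(
                a, b, loc=m[k], scale=sd[k], size=idx.size, random_state=rng
            )
    return pd.DataFrame(
        {
            "pair": [f"p{i:05d}" for i in range(n_pairs)],
            "identity": vals,
            "component": comp,
        }
    )


def default_trna_pool(rng: np.random.Generator) -> dict[str, int]:
    """A synthetic tRNA pool: Watson-Crick anticodons with uneven copy
    numbers, at least one decoder per amino acid."""
    pool: dict[str, int] = {}
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
    for aa in sorted(by_aa):
        codons = by_aa[aa]
        copies = rng.integers(0, 9, len(codons))
        if copies.sum() == 0:
            copies[int(rng.integers(0, len(codons)))] = int(rng.integers(1, 9))
        for codon, c in zip(codons, copies):
            if c > 0:
                pool[wc_anticodon(codon)] = int(c)
    return pool


def simulate_codon_genes(
    config: SimulationConfig,
    pool: Mapping[str, int],
    n_genes: int,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    """Coding sequences with or without codon bias toward the tRNA pool.

    Half the genes ("adapted") draw each codon proportionally to its
    relative adaptiveness within the synonymous family; the other half
    ("uniform") draw uniformly.  Sequences start with ATG and end with
    a single TAA stop.  Returns (sequences, bias flags).
    """
    from .tai import relative_adaptiveness

    if not pool:
        raise ValueError("tRNA pool must be nonempty")
    w = relative_adaptiveness(pool)
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
    aas = sorted(by_aa)
    sequences: dict[str, str] = {}
    flags: dict[str, str] = {}
    for i in range(n_genes):
        name = f"cds{i:04d}"
        adapted = i % 2 == 0
        codons = ["ATG"]
        for _ in range(config.cds_length_aa - 1):
            aa = aas[int(rng.integers(0, len(aas)))]
            if aa == "M":
                codons.append("ATG")
                continue
            options = by_aa[aa]
            if adapted:
                p = np.array([w[c] for c in options])
                p = p / p.sum()
                codons.append(options[int(rng.choice(len(options), p=p))])
            else:
                codons.append(options[int(rng.integers(0, len(options)))])
        codons.append("TAA")
        sequences[name] = "".join(codons)
        flags[name] = "adapted" if adapted else "uniform"
    return sequences, flags


def simulate_all(config: SimulationConfig, n_pairs: int = 10000, n_cds: int = 100) -> SimulatedGenome:
    """Run the full generator pipeline under one seed."""
    rng = np.random.default_rng(config.seed)
    ancestral = simulate_ancestral_genome(config, rng)
    karyotype, orders = simulate_karyotype(config, ancestral, rng)
    scaffolds, placements, truth = emit_scaffolds(config, karyotype, orders, ancestral, rng)
    identities = simulate_ortholog_identities(config, n_pairs, rng)
    truth.identity_classes = dict(zip(identities["pair"], identities["component"].astype(int)))
    pool = default_trna_pool(rng)
    cds, flags = simulate_codon_genes(config, pool, n_cds, rng)
    truth.codon_bias_flags = flags
    genome = SimulatedGenome(
        config, ancestral, karyotype, orders, scaffolds, placements, truth
    )
    genome.identities = identities  # type: ignore[attr-defined]
    genome.trna_pool = pool  # type: ignore[attr-defined]
    genome.coding = cds  # type: ignore[attr-defined]
    return genome


def _write_fasta(seqs: Mapping[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_all(genome: SimulatedGenome, outdir) -> None:
    """Emit every simulator output as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(genome.scaffolds, out / "scaffolds.fasta")
    with open(out / "placements.tsv", "w") as fh:
        for scaf in genome.placements:
            for p in genome.placements[scaf]:
                fh.write(f"{scaf}\t{p.start}\t{p.end}\t{p.gene}\t.\t{p.strand}\n")
    with open(out / "blocks.tsv", "w") as fh:
        for g in genome.ancestral:
            fh.write(f"{g.gene}\t{g.block}\t{g.index}\n")
    with open(out / "karyotype.json", "w") as fh:
        json.dump(genome.karyotype.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "gene_blocks": {k: list(v) for k, v in genome.truth.gene_blocks.items()},
                "scaffolds": genome.truth.scaffold_truth,
                "satellites": genome.truth.satellites,
                "identity_classes": genome.truth.identity_classes,
                "codon_bias_flags": genome.truth.codon_bias_flags,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    genome.identities.to_csv(out / "identities.tsv", sep="\t", index=False)
    _write_fasta(genome.coding, out / "coding.fasta")
    with open(out / "trna_pool.tsv", "w") as fh:
        for ac in sorted(genome.trna_pool):
            fh.write(f"{ac}\t{genome.trna_pool[ac]}\n")
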