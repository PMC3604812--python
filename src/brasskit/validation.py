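"""End-to-end parameter-recovery pipelines on simulated genomes.

These helpers wire the simulator to the analysis modules: paint the
simulated scaffolds from the (optionally noised) block table, detect
the planted satellite arrays, match scaffolds to the karyotype, and
score the result against ground truth.  They are what the package's
own validation suite runs; they contain no logic of their own beyond
plumbing and scoring.
"""

from __future__ import annotations



import numpy as np

from . import blockpaint, karyotype as kt, satellite
from .simulate import SimulatedGenome, SimulationConfig, simulate_all

# period bracket for the CentO-class satellite search used during assembly
CENTO_SEARCH = satellite.SatelliteParams(min_period=150, max_period=210)


def mislabel_genes(
    block_table: dict[str, tuple[str, int]],
    fraction: float,
    rng: np.random.Generator,
    alphabet: str | None = None,
) -> dict[str, tuple[str, int]]:
    """Reassign a fraction of genes to a random wrong block (noise model)."""
    if fraction <= 0:
        return dict(block_table)
    labels = sorted({b for b, _ in block_table.values()}) if alphabet is None else list(alphabet)
    out = dict(block_table)
    genes = sorted(block_table)
    hit = rng.random(len(genes)) < fraction
    for g, h in zip(genes, hit):
        if not h:
            continue
        true_label = block_table[g][0]
        others = [l for l in labels if l != true_label]
        out[g] = (others[int(rng.integers(0, len(others)))], int(rng.integers(0, 50)))
    return out


def assemble_simulated(
    genome: SimulatedGenome,
    block_table: dict[str, tuple[str, int]] | None = None,
    min_run: int = 3,
    max_interleave: int = 2,
    sat_params: satellite.SatelliteParams = CENTO_SEARCH,
    detect_satellites: bool = True,
):
    """Paint, detect satellites and match one simulated genome.

    Returns (plan, discrepancies, painted).
    """
    table = block_table if block_table is not None else genome.truth.gene_blocks
    painted = blockpaint.paint_all(
        genome.placements, table, min_run=min_run, max_interleave=max_interleave
    )
    if detect_satellites:
        arrays = satellite.scan_genome(genome.scaffolds, sat_params)
    else:
        arrays = [
            satellite.SatelliteArray(
                d["scaffold"], d["start"], d["end"], d["period"],
                (d["end"] - d["start"]) / d["period"], "", 0.0,
            )
            for d in genome.truth.satellites
        ]
    by_scaffold: dict[str, list[satellite.SatelliteArray]] = {}
    for a in arrays:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    lengths = {name: len(seq) for name, seq in genome.scaffolds.items()}
    plan, disc = kt.match_scaffolds(
        genome.karyotype, painted, by_scaffold, lengths
    )
    return plan, disc, painted


def scaffold_recovery_score(genome: SimulatedGenome, plan: kt.PlacementPlan) -> float:
    """Fraction of scaffolds placed on their true chromosome with their
    true orientation (unplaced scaffolds count as failures)."""
    truth = genome.truth.scaffold_truth
    correct = 0
    placed_chrom = {
        pl.scaffold: (chrom, pl.orientation)
        for chrom, pls in plan.chromosomes.items()
        for pl in pls
    }
    for scaf, t in truth.items():
        got = placed_chrom.get(scaf)
        if got is not None and got[0] == t["chromosome"] and got[1] == t["orientation"]:
            correct += 1
    return correct / len(truth)


def order_accuracy(genome: SimulatedGenome, plan: kt.PlacementPlan) -> float:
    """Fraction of correctly-chromosomed scaffolds whose within-chromosome
    rank order matches the ground truth."""
    truth = genome.truth.scaffold_truth
    ok = 0
    total = 0
    for chrom, pls in plan.chromosomes.items():
        on_chrom = [p.scaffold for p in pls if truth[p.scaffold]["chromosome"] == chrom]
        ranks = [truth[s]["rank"] for s in on_chrom]
        total += len(ranks)
        ok += sum(1 for a, b in zip(ranks, sorted(ranks)) if a == b)
    return ok / total if total else 0.0


def karyotype_recovery_trial(
    seed: int,
    noise_fraction: float = 0.0,
    n_scaffolds: int | None = None,
    config: SimulationConfig | None = None,
) -> float:
    """One seeded simulate -> paint -> assemble run; returns the
    scaffold recovery score."""
    rng = np.random.default_rng(seed + 777)
    if config is None:
        ns = n_scaffolds if n_scaffolds is not None else int(
            np.random.default_rng(seed).integers(30, 61)
        )
        config = SimulationConfig(seed=seed, n_scaffolds=ns)
    genome = simulate_all(config, n_pairs=0, n_cds=0)
    table = genome.truth.gene_blocks
    if noise_fraction > 0:
        table = mislabel_genes(table, noise_fraction, rng)
    plan, _, _ = assemble_simulated(genome, block_table=table)
    return scaffold_recovery_score(genome, plan)


def satellite_recovery_trial(seed: int, n_arrays: int = 5) -> tuple[int, int]:
    """Plant arrays with random periods in [150, 200] and re-detect them.

    Each array (>=20 copies, 1% per-base copy mutation) is embedded in
    random flanking sequence; returns (n recovered within +-1 bp of the
    true period, n planted).
    """
    rng = np.random.default_rng(seed)
    params = satellite.SatelliteParams(min_period=100, max_period=300)
    hits = 0
    for _ in range(n_arrays):
        period = int(rng.integers(150, 201))
        copies = int(rng.integers(20, 41))
        cfg = SimulationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            satellite_period=period,
            satellite_copies=(copies, copies),
        )
        from .simulate import _satellite_array, _rand_seq

        arr_rng = np.random.default_rng(cfg.seed)
        arr, _, _ = _satellite_array(cfg, arr_rng)
        flank_l = _rand_seq(arr_rng, 3000)
        flank_r = _rand_seq(arr_rng, 3000)
        found = satellite.find_arrays("s", flank_l + arr + flank_r, params)
        if any(abs(a.period - period) <= 1 for a in found):
            hits += 1
    return hits, n_arrays
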