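"""Synthetic-genome generator: determinism, conservation, ground truth."""

import filecmp
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from brasskit import tai
from brasskit.simulate import (
    SimulationConfig,
    default_trna_pool,
    emit_scaffolds,
    simulate_all,
    simulate_ancestral_genome,
    simulate_codon_genes,
    simulate_karyotype,
    simulate_ortholog_identities,
    write_all,
)


class TestConfig:
    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_blocks=27).validate()

    def test_fewer_scaffolds_than_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_scaffolds=3, n_chromosomes=7).validate()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(satellite_at_fraction=1.5).validate()


class TestAncestralGenome:
    def test_degenerate_single_block(self):
        cfg = SimulationConfig(n_blocks=1, genes_per_block=(5, 5), n_chromosomes=1, n_scaffolds=1)
        genes = simulate_ancestral_genome(cfg, np.random.default_rng(0))
        assert [g.block for g in genes] == ["A"] * 5
        assert [g.index for g in genes] == [0, 1, 2, 3, 4]

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=1)
        a = simulate_ancestral_genome(cfg, np.random.default_rng(1))
        b = simulate_ancestral_genome(cfg, np.random.default_rng(1))
        assert a == b

    def test_total_equals_independent_recount(self, rng):
        cfg = SimulationConfig(genes_per_block=(30, 60))
        genes = simulate_ancestral_genome(cfg, rng)
        per_block = Counter(g.block for g in genes)
        assert len(per_block) == 24
        assert all(30 <= n <= 60 for n in per_block.values())
        assert len(genes) == sum(per_block.values())
        # indices strictly increasing within each block
        for label in per_block:
            idx = [g.index for g in genes if g.block == label]
            assert idx == sorted(idx) and len(set(idx)) == len(idx)


class TestKaryotype:
    def test_gene_content_conserved_through_rearrangement(self, rng):
        cfg = SimulationConfig()
        ancestral = simulate_ancestral_genome(cfg, rng)
        karyo, orders = simulate_karyotype(cfg, ancestral, rng)
        rearranged = Counter(g for order in orders.values() for g, _ in order)
        assert rearranged == Counter(g.gene for g in ancestral)

    def test_seven_chromosomes_cover_24_blocks(self, rng):
        cfg = SimulationConfig(n_chromosomes=7, n_blocks=24)
        ancestral = simulate_ancestral_genome(cfg, rng)
        karyo, _ = simulate_karyotype(cfg, ancestral, rng)
        assert len(karyo.chromosomes) == 7
        all_blocks = [lab for c in karyo.chromosomes for _, lab in c.blocks]
        assert len(all_blocks) == 24 and len(set(all_blocks)) == 24
        assert all(len(c.blocks) >= 1 for c in karyo.chromosomes)
        for c in karyo.chromosomes:
            assert 0 <= c.centromere_after < max(len(c.blocks) - 1, 1)

    def test_minus_block_genes_descend(self, rng):
        cfg = SimulationConfig()
        ancestral = simulate_ancestral_genome(cfg, rng)
        karyo, orders = simulate_karyotype(cfg, ancestral, rng)
        table = {g.gene: (g.block, g.index) for g in ancestral}
        for chrom in karyo.chromosomes:
            order = orders[chrom.name]
            pos = 0
            for sign, label in chrom.blocks:
                block_len = sum(1 for g in ancestral if g.block == label)
                chunk = order[pos : pos + block_len]
                pos += block_len
                idx = [table[g][1] for g, _ in chunk]
                strands = {s for _, s in chunk}
                if sign == "+":
                    assert idx == sorted(idx) and strands == {"+"}
                else:
                    assert idx == sorted(idx, reverse=True) and strands == {"-"}


class TestEmitScaffolds:
    def test_ground_truth_complete(self, genome):
        assert set(genome.truth.scaffold_truth) == set(genome.scaffolds)
        placed = [p.gene for track in genome.placements.values() for p in track]
        assert Counter(placed) == Counter(g.gene for g in genome.ancestral)
        for d in genome.truth.satellites:
            assert d["scaffold"] in genome.scaffolds
            assert d["end"] - d["start"] == d["period"] * d["copies"]

    def test_satellite_interval_arithmetic(self):
        cfg = SimulationConfig(
            seed=5, satellite_copies=(40, 40), satellite_period=177, n_scaffolds=20
        )
        g = simulate_all(cfg, n_pairs=0, n_cds=0)
        for d in g.truth.satellites:
            assert d["end"] - d["start"] == 40 * 177

    def test_placement_sequences_match_scaffolds(self, genome):
        """Gene intervals are within bounds, sorted, non-overlapping."""
        for scaf, track in genome.placements.items():
            L = len(genome.scaffolds[scaf])
            prev_end = 0
            for p in sorted(track, key=lambda x: x.start):
                assert 0 <= p.start < p.end <= L
                assert p.start >= prev_end
                prev_end = p.end

    def test_flipped_single_block_scaffold_indices_decrease(self, genome):
        table = genome.truth.gene_blocks
        karyo_sign = {
            lab: sign
            for c in genome.karyotype.chromosomes
            for sign, lab in c.blocks
        }
        checked = 0
        for scaf, track in genome.placements.items():
            labels = {table[p.gene][0] for p in track}
            if len(labels) != 1 or len(track) < 2:
                continue
            (label,) = labels
            flip = genome.truth.scaffold_truth[scaf]["orientation"]
            idx = [table[p.gene][1] for p in sorted(track, key=lambda x: x.start)]
            ascending = karyo_sign[label] == "+"
            if flip == "-":
                ascending = not ascending
            assert idx == sorted(idx, reverse=not ascending)
            checked += 1
        assert checked > 0

    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_scaffolds=15)
        for d in ("a", "b"):
            write_all(simulate_all(cfg, n_pairs=200, n_cds=10), tmp_path / d)
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a",
            tmp_path / "b",
            [p.name for p in (tmp_path / "a").iterdir()],
            shallow=False,
        )
        assert not mismatch and not errors and match


class TestIdentityMixture:
    def test_pure_component_when_weight_one(self, rng):
        cfg = SimulationConfig(mixture_weight=1.0)
        df = simulate_ortholog_identities(cfg, 100, rng)
        assert (df["component"] == 0).all()

    def test_empty_table(self, rng):
        assert len(simulate_ortholog_identities(SimulationConfig(), 0, rng)) == 0

    def test_component_means_match_truncated_normal(self, rng):
        cfg = SimulationConfig()
        df = simulate_ortholog_identities(cfg, 10000, rng)
        for k in (0, 1):
            m, sd = cfg.identity_modes[k], cfg.identity_sds[k]
            a, b = (0 - m) / sd, (1 - m) / sd
            expected = stats.truncnorm.mean(a, b, loc=m, scale=sd)
            se = stats.truncnorm.std(a, b, loc=m, scale=sd) / np.sqrt(
                (df["component"] == k).sum()
            )
            sample = df.loc[df["component"] == k, "identity"].mean()
            assert abs(sample - expected) < 3 * se
        assert df["identity"].between(0, 1).all()


class TestCodonGenes:
    def test_structure(self, rng):
        pool = default_trna_pool(rng)
        seqs, flags = simulate_codon_genes(SimulationConfig(), pool, 10, rng)
        for name, s in seqs.items():
            assert len(s) % 3 == 0
            assert s.startswith("ATG") and s.endswith("TAA")
            internal = [s[i : i + 3] for i in range(3, len(s) - 3, 3)]
            assert not any(c in tai.STOP_CODONS for c in internal)
        assert set(flags.values()) == {"adapted", "uniform"}

    def test_adapted_usage_tracks_adaptiveness(self, rng):
        """Adapted genes favour high-w codons within each synonymous family."""
        pool = default_trna_pool(rng)
        w = tai.relative_adaptiveness(pool)
        seqs, flags = simulate_codon_genes(SimulationConfig(), pool, 60, rng)
        usage = Counter()
        for name, s in seqs.items():
            if flags[name] != "adapted":
                continue
            usage.update(s[i : i + 3] for i in range(0, len(s) - 3, 3))
        # Leu has 6 synonymous codons; the top-w codon should be used more
        # often than the bottom-w codon across adapted genes
        leu = [c for c in tai.SENSE_CODONS if tai.GENETIC_CODE[c] == "L"]
        top = max(leu, key=lambda c: w[c])
        bottom = min(leu, key=lambda c: w[c])
        assert usage[top] > usage[bottom]

    def test_adapted_genes_have_higher_tai(self, rng):
        pool = default_trna_pool(rng)
        seqs, flags = simulate_codon_genes(SimulationConfig(), pool, 100, rng)
        profile = tai.TAIProfile(dict(pool))
        vals = profile.tai_table(seqs)
        adapted = [vals[g] for g in vals if flags[g] == "adapted"]
        uniform = [vals[g] for g in vals if flags[g] == "uniform"]
        assert np.mean(adapted) > np.mean(uniform)
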