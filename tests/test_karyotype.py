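"""Karyotype-guided scaffold arrangement, AGP emission, discrepancies, SVG."""

import numpy as np
import pytest

from brasskit import blockpaint, karyotype as kt, validation
from brasskit.blockpaint import BlockSegment
from brasskit.simulate import Chromosome, KaryotypeDefinition, SimulationConfig, simulate_all


def seg(scaffold, block, orientation="+", start=0, end=1000, n=5, mean_index=10.0):
    return BlockSegment(scaffold, block, start, end, tuple(f"{scaffold}_{block}{i}" for i in range(n)), orientation, mean_index)


def karyo_1chrom(blocks, cen=0):
    return KaryotypeDefinition([Chromosome("Chr1", blocks, cen)])


class TestMatchScaffolds:
    def test_identity_match(self):
        karyo = karyo_1chrom([("+", "A"), ("-", "B"), ("+", "C")], cen=1)
        painted = {"s1": [seg("s1", "A"), seg("s1", "B", "-"), seg("s1", "C")]}
        plan, disc = kt.match_scaffolds(karyo, painted)
        assert plan.unplaced == []
        (pl,) = plan.chromosomes["Chr1"]
        assert (pl.scaffold, pl.orientation, pl.position) == ("s1", "+", 0)
        assert disc == []

    def test_reversed_scaffold_matches_minus(self):
        karyo = karyo_1chrom([("+", "A"), ("-", "B")], cen=0)
        # scaffold painted B+, A- reads as the reverse complement of +A -B
        painted = {"s1": [seg("s1", "B", "+"), seg("s1", "A", "-")]}
        plan, _ = kt.match_scaffolds(karyo, painted)
        (pl,) = plan.chromosomes["Chr1"]
        assert pl.orientation == "-"
        assert pl.blocks == ("A", "B")

    def test_unmatchable_scaffold_unplaced(self):
        karyo = karyo_1chrom([("+", "A"), ("+", "B")])
        painted = {"s1": [seg("s1", "B"), seg("s1", "A")]}  # order B,A matches only reversed
        plan, disc = kt.match_scaffolds(karyo, painted)
        # reversed match exists: B,A reversed is A,B -> placed with '-'
        assert plan.unplaced == []
        painted = {"s2": [seg("s2", "A"), seg("s2", "Z")]}
        plan, disc = kt.match_scaffolds(karyo, painted)
        assert plan.unplaced == ["s2"]
        assert disc[0].kind == "unplaced_scaffold"

    def test_duplicate_interior_claim_conflicts(self):
        karyo = karyo_1chrom([("+", "A"), ("+", "B"), ("+", "C")])
        big = {"genes": 10}
        painted = {
            "s1": [seg("s1", "A", n=8), seg("s1", "B", n=8), seg("s1", "C", n=8)],
            "s2": [seg("s2", "A", n=3), seg("s2", "B", n=3), seg("s2", "C", n=3)],
        }
        plan, disc = kt.match_scaffolds(karyo, painted)
        assert plan.unplaced == ["s2"]
        assert any(d.kind == "order_conflict" for d in disc)

    def test_within_block_ordering_by_mean_index(self):
        karyo = karyo_1chrom([("+", "A")])
        painted = {
            "early": [seg("early", "A", mean_index=5.0)],
            "late": [seg("late", "A", mean_index=25.0)],
        }
        plan, _ = kt.match_scaffolds(karyo, painted)
        assert [p.scaffold for p in plan.chromosomes["Chr1"]] == ["early", "late"]
        karyo_minus = karyo_1chrom([("-", "A")])
        plan, _ = kt.match_scaffolds(karyo_minus, painted)
        assert [p.scaffold for p in plan.chromosomes["Chr1"]] == ["late", "early"]

    def test_satellite_terminus_faces_centromere(self):
        from brasskit.satellite import SatelliteArray

        karyo = karyo_1chrom([("+", "A"), ("+", "B"), ("+", "C")], cen=1)
        # scaffold on block A (left of centromere): satellite must face right.
        # Painted sign agrees with '+' but the satellite sits left-terminal,
        # so the satellite evidence flips it and logs a conflict.
        painted = {"s1": [seg("s1", "A", "+")]}
        sats = {"s1": [SatelliteArray("s1", 0, 7080, 177, 40.0, "", 0.7)]}
        plan, disc = kt.match_scaffolds(karyo, painted, sats, {"s1": 100_000})
        (pl,) = plan.chromosomes["Chr1"]
        assert pl.orientation == "-"
        assert any(d.kind == "orientation_conflict" for d in disc)

    def test_noise_free_simulation_fully_recovered(self, genome):
        plan, disc, painted = validation.assemble_simulated(genome)
        assert validation.scaffold_recovery_score(genome, plan) == 1.0
        assert validation.order_accuracy(genome, plan) == 1.0
        assert plan.unplaced == []


class TestBuildPseudomolecules:
    def test_two_scaffold_arithmetic(self):
        plan = kt.PlacementPlan(
            {"Chr1": [kt.ScaffoldPlacement("s1", "+", ("A",), 0),
                      kt.ScaffoldPlacement("s2", "+", ("B",), 1)]},
            [],
        )
        seqs = {"s1": "A" * 1000, "s2": "C" * 2000}
        chroms, agp = kt.build_pseudomolecules(plan, seqs, inter_scaffold_gap=100)
        assert len(chroms["Chr1"]) == 3100
        assert [int(r[2]) for r in agp] == [1000, 1100, 3100]
        assert [r[4] for r in agp] == ["W", "U", "W"]

    def test_single_scaffold_identity(self):
        plan = kt.PlacementPlan(
            {"Chr1": [kt.ScaffoldPlacement("s1", "+", ("A",), 0)]}, []
        )
        chroms, agp = kt.build_pseudomolecules(plan, {"s1": "ACGTT"})
        assert chroms["Chr1"] == "ACGTT"
        assert len(agp) == 1

    def test_minus_scaffold_reverse_complemented(self):
        plan = kt.PlacementPlan(
            {"Chr1": [kt.ScaffoldPlacement("s1", "-", ("A",), 0)]}, []
        )
        chroms, _ = kt.build_pseudomolecules(plan, {"s1": "AACG"})
        assert chroms["Chr1"] == "CGTT"

    def test_missing_scaffold_rejected(self):
        plan = kt.PlacementPlan(
            {"Chr1": [kt.ScaffoldPlacement("nope", "+", ("A",), 0)]}, []
        )
        with pytest.raises(KeyError):
            kt.build_pseudomolecules(plan, {})

    def test_agp_round_trip_recovers_scaffolds(self, genome, tmp_path):
        plan, _, _ = validation.assemble_simulated(genome)
        chroms, agp = kt.build_pseudomolecules(plan, genome.scaffolds)
        path = tmp_path / "x.agp"
        kt.write_agp(agp, path)
        rows = kt.read_agp(path)
        recovered = kt.extract_components(rows, chroms)
        placed = {
            pl.scaffold for pls in plan.chromosomes.values() for pl in pls
        }
        assert set(recovered) == placed
        for name in recovered:
            assert recovered[name] == genome.scaffolds[name]

    def test_sequence_conservation(self, genome):
        plan, _, _ = validation.assemble_simulated(genome)
        chroms, _ = kt.build_pseudomolecules(plan, genome.scaffolds, 100)
        for chrom, pls in plan.chromosomes.items():
            expect = sum(len(genome.scaffolds[p.scaffold]) for p in pls)
            expect += 100 * max(len(pls) - 1, 0)
            assert len(chroms[chrom]) == expect
        placed = [p.scaffold for pls in plan.chromosomes.values() for p in pls]
        assert len(placed) == len(set(placed))
        assert len(placed) + len(plan.unplaced) == len(genome.scaffolds)


class TestDiscrepancyReport:
    def test_perfect_assembly_is_clean(self, genome):
        plan, disc, painted = validation.assemble_simulated(genome)
        report = kt.discrepancy_report(plan, genome.karyotype, painted, disc)
        assert report == []

    def test_missing_block_reported(self):
        karyo = karyo_1chrom([("+", "A"), ("+", "B")])
        painted = {"s1": [seg("s1", "A")]}
        plan, disc = kt.match_scaffolds(karyo, painted)
        report = kt.discrepancy_report(plan, karyo, painted, disc)
        missing = [d for d in report if d.kind == "missing_block"]
        assert [d.entities for d in missing] == [("B",)]

    def test_split_block_reported(self):
        karyo = KaryotypeDefinition(
            [
                Chromosome("Chr1", [("+", "A"), ("+", "M")], 0),
                Chromosome("Chr2", [("+", "B"), ("+", "M2")], 0),
            ]
        )
        # M segments end up on scaffolds of two different chromosomes
        painted = {
            "s1": [seg("s1", "A", n=6), seg("s1", "M", n=3)],
            "s2": [seg("s2", "B", n=6), seg("s2", "M", n=3)],
        }
        karyo.chromosomes[1].blocks = [("+", "B"), ("+", "M")]
        plan, disc = kt.match_scaffolds(karyo, painted)
        report = kt.discrepancy_report(plan, karyo, painted, disc)
        assert any(d.kind == "split_block" and d.entities[0] == "M" for d in report)


class TestRenderKaryotype:
    def test_empty_plan_has_header_only(self):
        karyo = KaryotypeDefinition([])
        svg = kt.render_digital_karyotype(kt.PlacementPlan({}, []), {}, karyo)
        assert svg.startswith("<?xml")
        assert "<rect" not in svg

    def test_rect_count_equals_placed_blocks(self, genome):
        plan, _, painted = validation.assemble_simulated(genome)
        svg = kt.render_digital_karyotype(plan, painted, genome.karyotype)
        n_blocks = sum(
            len(pl.blocks) for pls in plan.chromosomes.values() for pl in pls
        )
        assert svg.count("<rect") == n_blocks
        assert svg.count("<circle") == len(genome.karyotype.chromosomes)

    def test_deterministic(self, genome):
        plan, _, painted = validation.assemble_simulated(genome)
        a = kt.render_digital_karyotype(plan, painted, genome.karyotype)
        b = kt.render_digital_karyotype(plan, painted, genome.karyotype)
        assert a == b


def test_recovery_with_label_noise():
    """With 5% mislabeled genes most scaffolds still place correctly."""
    scores = [
        validation.karyotype_recovery_trial(seed, noise_fraction=0.05)
        for seed in range(5)
    ]
    assert np.mean(scores) >= 0.90
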