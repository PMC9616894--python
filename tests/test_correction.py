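"""Exchange plans, snapping, application, and conservation invariants."""

from collections import Counter

import pytest

from triohap.correction import (
    ExchangePlan,
    apply_correction,
    exchange_segments,
    plan_correction,
    plans_from_truth,
    split_component,
)
from triohap.io_formats import (
    AgpComponent,
    DiploidAssembly,
    GeneLocus,
    LocusCatalog,
    SeqRecord,
    format_seq_id,
)
from triohap.parentage import PairedSwitch


class TestSplitComponent:
    def test_plus_orientation_subranges(self):
        comp = AgpComponent("o", 100, 200, "tg", component_beg=0)
        left, right = split_component(comp, 130)
        assert (left.object_start, left.object_end) == (100, 130)
        assert (left.component_beg, left.component_end) == (0, 30)
        assert (right.component_beg, right.component_end) == (30, 100)

    def test_minus_orientation_mirrored(self):
        comp = AgpComponent("o", 100, 200, "tg", orientation="-", component_beg=0)
        left, right = split_component(comp, 130)
        assert (left.component_beg, left.component_end) == (70, 100)
        assert (right.component_beg, right.component_end) == (0, 70)

    def test_cut_outside_span_is_noop(self):
        comp = AgpComponent("o", 100, 200, "tg")
        assert split_component(comp, 100) == [comp]
        assert split_component(comp, 250) == [comp]


def _paired(chrom, iv1, iv2):
    return PairedSwitch(
        genome="g", chrom_index=chrom, interval_hap1=iv1, interval_hap2=iv2,
        upstream_species_hap1="spA", downstream_species_hap1="spB",
    )


def _toy_assembly():
    seq1 = "A" * 10_000
    seq2 = "C" * 10_000
    comps = []
    for hap, edges in ((1, [0, 4_000, 10_000]), (2, [0, 7_000, 10_000])):
        for i, (a, b) in enumerate(zip(edges, edges[1:])):
            comps.append(
                AgpComponent(format_seq_id(1, hap), a, b, f"tg_h{hap}_{i}")
            )
    return DiploidAssembly(
        genome_name="g",
        chromosomes={
            (1, 1): SeqRecord(id=format_seq_id(1, 1), sequence=seq1),
            (1, 2): SeqRecord(id=format_seq_id(1, 2), sequence=seq2),
        },
        components=comps,
    )


class TestPlanCorrection:
    def test_interval_spanning_junction_snaps_to_it(self):
        asm = _toy_assembly()
        plans = plan_correction([_paired(1, (3_900, 4_100), (3_900, 4_100))], asm)
        (plan,) = plans
        assert plan.cut_hap1 == 4_000  # junction inside the interval
        assert plan.cut_hap2 == 4_000  # hap2 has no junction there: midpoint

    def test_no_junction_in_interval_uses_midpoint(self):
        asm = _toy_assembly()
        plans = plan_correction([_paired(1, (5_000, 5_500), (5_000, 5_500))], asm)
        (plan,) = plans
        assert plan.cut_hap1 == 5_250
        assert plan.cut_hap2 == 5_250

    def test_junction_cut_and_component_split_in_one_plan(self):
        """Haplotype 1 cuts at a contig junction while haplotype 2 must
        split a component: both recorded in the same plan."""
        asm = _toy_assembly()
        plans = plan_correction([_paired(1, (3_950, 4_050), (3_950, 4_050))], asm)
        (plan,) = plans
        assert plan.cut_hap1 == 4_000
        assert plan.cut_hap2 == 4_000
        corrected, _cat, _ = apply_correction(asm, None, plans)
        # hap1 keeps its whole first contig; the exchanged tail starts with
        # the split remainder of hap2's spanning contig (a sub-range)
        comps1 = corrected.components_of(1, 1)
        assert [c.component_id for c in comps1] == ["tg_h1_0", "tg_h2_0", "tg_h2_1"]
        split_piece = comps1[1]
        assert (split_piece.object_start, split_piece.object_end) == (4_000, 7_000)
        assert (split_piece.component_beg, split_piece.component_end) == (4_000, 7_000)
        # hap2 keeps the head of its split contig and gains hap1's tail contig
        comps2 = corrected.components_of(1, 2)
        assert [c.component_id for c in comps2] == ["tg_h2_0", "tg_h1_1"]
        assert (comps2[0].component_beg, comps2[0].component_end) == (0, 4_000)

    def test_overlapping_plans_rejected(self):
        asm = _toy_assembly()
        with pytest.raises(ValueError, match="overlap"):
            plan_correction(
                [
                    _paired(1, (5_000, 5_100), (5_000, 5_100)),
                    _paired(1, (5_000, 5_100), (5_000, 5_100)),
                ],
                asm,
            )


class TestApplyCorrection:
    def test_empty_plan_list_is_identity(self, small_trio):
        asm = small_trio.assemblies["AxB"]
        cat = small_trio.catalogs["AxB"]
        asm2, cat2, dropped = apply_correction(asm, cat, [])
        assert dropped == 0
        assert {k: r.sequence for k, r in asm2.chromosomes.items()} == {
            k: r.sequence for k, r in asm.chromosomes.items()
        }

    def test_truth_plans_restore_pristine_state(self, small_trio):
        for genome in small_trio.design.genomes:
            plans = plans_from_truth(small_trio.truth_switches, genome)
            asm, cat, dropped = apply_correction(
                small_trio.assemblies[genome], small_trio.catalogs[genome], plans
            )
            assert dropped == 0
            pristine = small_trio.pristine_assemblies[genome]
            for key, rec in pristine.chromosomes.items():
                assert asm.chromosomes[key].sequence == rec.sequence
            want = {
                (g.gene_id, g.unit, g.start, g.end)
                for g in small_trio.pristine_catalogs[genome]
            }
            assert {(g.gene_id, g.unit, g.start, g.end) for g in cat} == want

    def test_base_multiset_conserved(self, small_trio):
        genome = "BxC"
        plans = plans_from_truth(small_trio.truth_switches, genome)
        asm, _cat, _ = apply_correction(
            small_trio.assemblies[genome], small_trio.catalogs[genome], plans
        )
        for chrom in (1, 2):
            before = Counter(
                small_trio.assemblies[genome].sequence(chrom, 1)
            ) + Counter(small_trio.assemblies[genome].sequence(chrom, 2))
            after = Counter(asm.sequence(chrom, 1)) + Counter(asm.sequence(chrom, 2))
            assert before == after

    def test_applying_twice_restores_input(self, small_trio):
        genome = "AxC"
        plans = plans_from_truth(small_trio.truth_switches, genome)
        asm0 = small_trio.assemblies[genome]
        cat0 = small_trio.catalogs[genome]
        asm1, cat1, _ = apply_correction(asm0, cat0, plans)
        asm2, cat2, _ = apply_correction(asm1, cat1, plans)
        assert {k: r.sequence for k, r in asm2.chromosomes.items()} == {
            k: r.sequence for k, r in asm0.chromosomes.items()
        }
        assert {(g.gene_id, g.unit, g.start) for g in cat2} == {
            (g.gene_id, g.unit, g.start) for g in cat0
        }

    def test_corrected_agp_still_tiles(self, small_trio):
        genome = "AxB"
        plans = plans_from_truth(small_trio.truth_switches, genome)
        asm, _cat, _ = apply_correction(
            small_trio.assemblies[genome], small_trio.catalogs[genome], plans
        )
        asm.validate_components()

    def test_locus_crossing_cut_dropped_and_counted(self):
        asm = _toy_assembly()
        cat = LocusCatalog(
            "g",
            [
                GeneLocus(gene_id="spanning", chrom_index=1, haplotype=1,
                          start=4_900, end=5_100),
                GeneLocus(gene_id="before", chrom_index=1, haplotype=1,
                          start=100, end=300),
                GeneLocus(gene_id="after", chrom_index=1, haplotype=2,
                          start=6_000, end=6_200),
            ],
        )
        plan = ExchangePlan(genome="g", chrom_index=1, cut_hap1=5_000, cut_hap2=5_000)
        asm2, cat2, dropped = apply_correction(asm, cat, [plan])
        assert dropped == 1
        ids = {g.gene_id for g in cat2}
        assert ids == {"before", "after"}
        # the retained downstream locus moved to the other haplotype
        assert cat2.by_id("after").haplotype == 1

    def test_wrong_genome_plan_rejected(self, small_trio):
        plan = ExchangePlan(genome="nope", chrom_index=1, cut_hap1=10, cut_hap2=10)
        with pytest.raises(ValueError):
            apply_correction(
                small_trio.assemblies["AxB"], small_trio.catalogs["AxB"], [plan]
            )


class TestEndToEndCorrection:
    def test_redetection_after_truth_correction_is_empty(self, small_trio):
        from triohap.pipeline import compute_best_hit_tables, detect_trio_switches

        corrected_asm, corrected_cat = {}, {}
        for genome in small_trio.design.genomes:
            plans = plans_from_truth(small_trio.truth_switches, genome)
            asm, cat, _ = apply_correction(
                small_trio.assemblies[genome], small_trio.catalogs[genome], plans
            )
            corrected_asm[genome] = asm
            corrected_cat[genome] = cat
        tables = compute_best_hit_tables(
            corrected_asm, corrected_cat, small_trio.design
        )
        _profiles, paired, uncallable = detect_trio_switches(
            corrected_cat, tables, small_trio.design, (1, 2)
        )
        assert uncallable == []
        assert all(not events for events in paired.values())
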