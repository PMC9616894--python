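"""Generator: ancestors, hybrids, switch injection, and their invariants."""

from collections import Counter

import numpy as np
import pytest

from triohap.correction import exchange_segments
from triohap.synthetic import (
    AncestorModel,
    EditPlan,
    HybridDesign,
    compose_hybrids,
    inject_switches,
    mutate_sequence,
    ortholog_id,
    simulate_ancestors,
    simulate_trio,
)


class TestAncestorModel:
    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            AncestorModel(snp_rate=0.5)

    def test_indel_sv_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            AncestorModel(indel_max=60)
        with pytest.raises(ValueError):
            AncestorModel(sv_length_range=(40, 100))

    def test_gene_placement_infeasible_rejected(self):
        model = AncestorModel(
            chrom_length=10_000, n_genes_per_chrom=20, gene_length=1_000
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate_ancestors(model)


class TestHybridDesign:
    def test_default_is_triangle(self):
        design = HybridDesign()
        assert design.species == ("spA", "spB", "spC")
        assert design.shared_species("AxB", "BxC") == "spB"
        assert design.partner_sharing("AxB", "spA") == "AxC"

    def test_non_triangle_rejected(self):
        with pytest.raises(ValueError, match="triangle"):
            HybridDesign(
                genomes=("g1", "g2", "g3"),
                pedigree={
                    "g1": frozenset(("a", "b")),
                    "g2": frozenset(("a", "b")),
                    "g3": frozenset(("c", "d")),
                },
            )


class TestEditPlan:
    def test_apply_and_lift(self):
        seq = "AAAACCCCGGGGTTTT"
        plan = EditPlan(
            [("snp", 1, "G"), ("del", 4, 2), ("ins", 10, "TT")]
        )
        assert plan.apply(seq) == "AGAACCGGTTGGTTTT".replace("TTGG", "TTGG")
        # explicit: A G A A | del CC | CCGG | ins TT | GGTTTT
        assert plan.apply(seq) == "AGAA" + "CCGG" + "TT" + "GGTTTT"
        assert plan.lift(0) == 0
        assert plan.lift(4) == 4
        assert plan.lift(6) == 4  # right after the deletion
        assert plan.lift(10) == 8
        assert plan.lift(11) == 11  # beyond the insertion
        assert plan.lift(5) == 4  # inside the deletion collapses to its start


class TestMutateSequence:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 100
        res = mutate_sequence(rng, seq, [], 0.0, 0.0, sv_count=0)
        assert res.sequence == seq

    def test_sv_deletions_stay_intergenic(self):
        rng = np.random.default_rng(1)
        seq = "ACGT" * 5_000
        genes = [(i * 1_000, i * 1_000 + 400) for i in range(1, 15)]
        res = mutate_sequence(
            rng, seq, genes, 0.0, 0.0, sv_count=5, sv_length_range=(100, 300)
        )
        for edit in res.plan.edits:
            if edit[0] == "del":
                s, length = edit[1], edit[2]
                for gs, ge in genes:
                    assert edit[1] + length <= gs or edit[1] >= ge

    def test_genes_survive_lifting(self):
        rng = np.random.default_rng(2)
        seq = "ACGT" * 10_000
        genes = [(i * 2_000, i * 2_000 + 900) for i in range(1, 18)]
        res = mutate_sequence(
            rng, seq, genes, 0.01, 0.004, sv_count=4, sv_length_range=(100, 500)
        )
        for gs, ge in genes:
            ls, le = res.plan.lift_interval(gs, ge)
            assert 0 <= ls < le <= len(res.sequence)


class TestSimulateAncestors:
    def test_zero_divergence_identical_ancestors(self):
        model = AncestorModel(
            n_chromosomes=1, chrom_length=30_000, n_genes_per_chrom=10,
            snp_rate=0.0, indel_rate=0.0, sv_count_per_chrom=0, seed=3,
        )
        anc = simulate_ancestors(model)
        a, b, c = anc.species
        assert anc.sequences[a][1] == anc.sequences[b][1] == anc.sequences[c][1]

    def test_realized_snp_count_within_binomial_bound(self):
        # 1 Mbp at snp_rate 0.005: +/-4 sigma of Binomial(1e6, 0.005)
        model = AncestorModel(
            n_chromosomes=1, chrom_length=1_000_000, n_genes_per_chrom=50,
            snp_rate=0.005, indel_rate=0.0, sv_count_per_chrom=0,
            species_scales=(1.0, 1.0), seed=5,
        )
        anc = simulate_ancestors(model)
        for sp in anc.species[1:]:
            assert 4_717 <= anc.snp_count(sp) <= 5_283

    def test_same_seed_byte_identical(self):
        model = AncestorModel(
            n_chromosomes=1, chrom_length=40_000, n_genes_per_chrom=15, seed=9
        )
        a1 = simulate_ancestors(model)
        a2 = simulate_ancestors(model)
        for sp in a1.species:
            assert a1.sequences[sp] == a2.sequences[sp]

    def test_ortholog_counts_equal_after_lifting(self):
        model = AncestorModel(
            n_chromosomes=2, chrom_length=60_000, n_genes_per_chrom=20, seed=13
        )
        anc = simulate_ancestors(model)
        ids = {
            sp: sorted(g.gene_id for g in anc.catalogs[sp])
            for sp in anc.species
        }
        assert ids[anc.species[0]] == ids[anc.species[1]] == ids[anc.species[2]]


class TestComposeHybrids:
    def test_noise0_shared_haplotypes_identical(self, noise0_trio):
        design = noise0_trio.design
        for g1 in design.genomes:
            for g2 in design.genomes:
                if g1 >= g2:
                    continue
                sp = design.shared_species(g1, g2)
                for chrom in (1,):
                    h1 = next(
                        h for (g, c, h), s in noise0_trio.labels.items()
                        if g == g1 and c == chrom and s == sp
                    )
                    h2 = next(
                        h for (g, c, h), s in noise0_trio.labels.items()
                        if g == g2 and c == chrom and s == sp
                    )
                    assert (
                        noise0_trio.assemblies[g1].sequence(chrom, h1)
                        == noise0_trio.assemblies[g2].sequence(chrom, h2)
                    )

    def test_each_species_in_exactly_two_genomes(self, small_trio):
        counts = Counter()
        for (genome, chrom, _hap), sp in small_trio.labels.items():
            if chrom == 1:
                counts[sp] += 1
        assert set(counts.values()) == {2}

    def test_agp_components_tile_pseudomolecules(self, small_trio):
        for asm in small_trio.pristine_assemblies.values():
            asm.validate_components()  # raises on any gap/overlap
            for (chrom, hap), rec in asm.chromosomes.items():
                comps = asm.components_of(chrom, hap)
                assert comps[0].object_start == 0
                assert comps[-1].object_end == len(rec)
                assert 2 <= len(comps) <= 6

    def test_non_triangle_design_rejected(self):
        model = AncestorModel(
            n_chromosomes=1, chrom_length=30_000, n_genes_per_chrom=10, seed=1
        )
        anc = simulate_ancestors(model)
        bad = HybridDesign()
        bad.pedigree = {
            "AxB": frozenset(("spA", "spB")),
            "BxC": frozenset(("spA", "spB")),
            "AxC": frozenset(("spA", "spC")),
        }
        with pytest.raises(ValueError):
            compose_hybrids(anc, bad)


class TestInjectSwitches:
    def test_k0_is_noop(self, small_trio):
        asm = small_trio.pristine_assemblies["AxB"]
        cat = small_trio.pristine_catalogs["AxB"]
        rng = np.random.default_rng(0)
        asm2, cat2, truth = inject_switches(asm, cat, 0, rng)
        assert truth == []
        assert asm2 is asm and cat2 is cat

    def test_single_switch_is_suffix_exchange(self):
        model = AncestorModel(
            n_chromosomes=1, chrom_length=50_000, n_genes_per_chrom=15, seed=21
        )
        trio = simulate_trio(model=model, switches_per_genome=1)
        genome = trio.truth_switches[0].genome
        t = trio.truth_switches[0]
        pre = trio.pristine_assemblies[genome]
        post = trio.assemblies[genome]
        p = t.breakpoint
        assert post.sequence(t.chrom_index, 1)[p:] == pre.sequence(t.chrom_index, 2)[p:]
        assert post.sequence(t.chrom_index, 2)[p:] == pre.sequence(t.chrom_index, 1)[p:]
        assert post.sequence(t.chrom_index, 1)[:p] == pre.sequence(t.chrom_index, 1)[:p]

    def test_injection_is_involution(self, small_trio):
        """Re-exchanging at every truth breakpoint restores the input."""
        for genome in small_trio.design.genomes:
            asm = small_trio.assemblies[genome]
            cat = small_trio.catalogs[genome]
            for t in small_trio.truth_switches:
                if t.genome != genome:
                    continue
                asm, cat, _ = exchange_segments(
                    asm, cat, t.chrom_index, t.breakpoint, t.breakpoint
                )
            pre = small_trio.pristine_assemblies[genome]
            for key, rec in pre.chromosomes.items():
                assert asm.chromosomes[key].sequence == rec.sequence
            pre_loci = {
                (g.gene_id, g.unit, g.start) for g in small_trio.pristine_catalogs[genome]
            }
            assert {(g.gene_id, g.unit, g.start) for g in cat} == pre_loci

    def test_base_multiset_invariant_per_chromosome(self, small_trio):
        for genome in small_trio.design.genomes:
            pre = small_trio.pristine_assemblies[genome]
            post = small_trio.assemblies[genome]
            for chrom in (1, 2):
                before = Counter(pre.sequence(chrom, 1)) + Counter(pre.sequence(chrom, 2))
                after = Counter(post.sequence(chrom, 1)) + Counter(post.sequence(chrom, 2))
                assert before == after

    def test_ortholog_multiset_conserved_over_haplotype_pair(self, small_trio):
        """Switches move loci between haplotypes but the chromosome pair as
        a whole keeps both copies of every ortholog."""
        for genome in small_trio.design.genomes:
            post = small_trio.catalogs[genome]
            pre = small_trio.pristine_catalogs[genome]
            for chrom in (1, 2):
                combined_post = Counter(
                    ortholog_id(g.gene_id)
                    for h in (1, 2)
                    for g in post.loci_of(chrom, h)
                )
                combined_pre = Counter(
                    ortholog_id(g.gene_id)
                    for h in (1, 2)
                    for g in pre.loci_of(chrom, h)
                )
                assert combined_post == combined_pre
                assert set(combined_post.values()) == {2}

    def test_breakpoints_sorted_and_separated(self, small_trio):
        by_key = {}
        for t in small_trio.truth_switches:
            by_key.setdefault((t.genome, t.chrom_index), []).append(t.breakpoint)
        for bps in by_key.values():
            assert bps == sorted(bps)
            assert all(b - a > 1_000 for a, b in zip(bps, bps[1:]))


class TestDeterminism:
    def test_full_trio_same_seed_identical(self, small_model):
        t1 = simulate_trio(model=small_model, switches_per_genome=3)
        t2 = simulate_trio(model=small_model, switches_per_genome=3)
        for genome in t1.design.genomes:
            a1, a2 = t1.assemblies[genome], t2.assemblies[genome]
            assert {k: r.sequence for k, r in a1.chromosomes.items()} == {
                k: r.sequence for k, r in a2.chromosomes.items()
            }
        assert [
            (t.genome, t.chrom_index, t.breakpoint) for t in t1.truth_switches
        ] == [(t.genome, t.chrom_index, t.breakpoint) for t in t2.truth_switches]
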