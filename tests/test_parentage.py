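"""Similarity matrix, parent labeling, voting profiles, switch detection."""

import itertools

import pytest

from triohap.io_formats import GeneLocus
from triohap.parentage import (
    AMBIGUOUS,
    AssignmentProfile,
    HaplotypeSimilarityMatrix,
    ProfileEntry,
    SwitchEvent,
    assign_parent_labels,
    build_profile,
    build_similarity_matrix,
    detect_switches,
    pair_switch_events,
)
from triohap.similarity import BestHitTable, LocusMatch
from triohap.synthetic import HybridDesign


def _locus(gene_id, chrom=1, hap=1, start=0):
    return GeneLocus(
        gene_id=gene_id, chrom_index=chrom, haplotype=hap,
        start=start, end=start + 100,
    )


def _match(query, target, target_genome, identity):
    return LocusMatch(
        query=query, target=target, target_genome=target_genome,
        identity=identity, coverage_query=1.0, coverage_target=1.0,
    )


class TestSimilarityMatrix:
    def test_pooled_mean_of_both_directions(self):
        t_g1 = BestHitTable()
        t_g1.offer(_match(_locus("a1", hap=1), _locus("b1", hap=1), "g2", 0.9))
        t_g1.offer(_match(_locus("a2", hap=1, start=200), _locus("b2", hap=1, start=200), "g2", 0.8))
        t_g2 = BestHitTable()
        t_g2.offer(_match(_locus("b1", hap=1), _locus("a1", hap=1), "g1", 0.7))
        matrix = build_similarity_matrix({"g1": t_g1, "g2": t_g2}, 1)
        assert matrix.entry(("g1", 1), ("g2", 1)) == pytest.approx(0.8)
        assert matrix.support_of(("g1", 1), ("g2", 1)) == 3
        assert matrix.is_low_support(("g1", 1), ("g2", 1))

    def test_empty_tables_all_entries_flagged(self):
        matrix = build_similarity_matrix({"g1": BestHitTable()}, 1)
        assert matrix.entry(("g1", 1), ("g2", 1)) is None
        assert matrix.is_low_support(("g1", 1), ("g2", 1))

    def test_noise0_shared_entries_exactly_one(self, noise0_trio, clean_tables):
        from triohap.pipeline import compute_best_hit_tables

        tables = compute_best_hit_tables(
            noise0_trio.assemblies, noise0_trio.catalogs, noise0_trio.design
        )
        matrix = build_similarity_matrix(tables, 1)
        design = noise0_trio.design
        for g1, g2 in itertools.combinations(design.genomes, 2):
            sp = design.shared_species(g1, g2)
            h1 = next(h for h in (1, 2) if noise0_trio.labels[(g1, 1, h)] == sp)
            h2 = next(h for h in (1, 2) if noise0_trio.labels[(g2, 1, h)] == sp)
            assert matrix.entry((g1, h1), (g2, h2)) == 1.0


def _matrix_from_labels(design, truth_labels, shared_value=0.85, other_value=0.74):
    """Construct a matrix whose shared-species entries stand out."""
    units = [(g, h) for g in design.genomes for h in (1, 2)]
    matrix = HaplotypeSimilarityMatrix(chrom_index=1, units=units)
    for u, v in itertools.combinations(units, 2):
        if u[0] == v[0]:
            continue
        value = shared_value if truth_labels[u] == truth_labels[v] else other_value
        key = HaplotypeSimilarityMatrix._key(u, v)
        matrix.values[key] = value
        matrix.support[key] = 50
    return matrix


def _oracle_best_labeling(matrix, design):
    """Independent enumeration of all 8 orientations."""
    best = None
    for bits in itertools.product((0, 1), repeat=3):
        labels = {}
        for genome, bit in zip(design.genomes, bits):
            a, b = sorted(design.pedigree[genome])
            labels[(genome, 1)] = a if bit == 0 else b
            labels[(genome, 2)] = b if bit == 0 else a
        score = 0.0
        for g1, g2 in itertools.combinations(design.genomes, 2):
            sp = design.shared_species(g1, g2)
            u = next(k for k, s in labels.items() if k[0] == g1 and s == sp)
            v = next(k for k, s in labels.items() if k[0] == g2 and s == sp)
            score += matrix.entry(u, v) or 0.0
        if best is None or score > best[0]:
            best = (score, labels)
    return best[1]


class TestAssignParentLabels:
    @pytest.mark.parametrize("bits", list(itertools.product((0, 1), repeat=3)))
    def test_recovers_designed_labeling(self, triangle_design, bits):
        truth = {}
        for genome, bit in zip(triangle_design.genomes, bits):
            a, b = sorted(triangle_design.pedigree[genome])
            truth[(genome, 1)] = a if bit == 0 else b
            truth[(genome, 2)] = b if bit == 0 else a
        matrix = _matrix_from_labels(triangle_design, truth)
        labeling = assign_parent_labels(matrix, triangle_design)
        assert labeling.labels == truth
        assert labeling.labels == _oracle_best_labeling(matrix, triangle_design)
        assert not labeling.ambiguous

    def test_all_entries_equal_is_ambiguous(self, triangle_design):
        truth = {
            (g, h): sorted(triangle_design.pedigree[g])[h - 1]
            for g in triangle_design.genomes for h in (1, 2)
        }
        matrix = _matrix_from_labels(triangle_design, truth, 0.8, 0.8)
        labeling = assign_parent_labels(matrix, triangle_design)
        assert labeling.ambiguous

    def test_row_swap_swaps_one_genomes_labels_only(self, triangle_design):
        truth = {
            (g, h): sorted(triangle_design.pedigree[g])[h - 1]
            for g in triangle_design.genomes for h in (1, 2)
        }
        matrix = _matrix_from_labels(triangle_design, truth)
        swapped_truth = dict(truth)
        swapped_truth[("AxB", 1)], swapped_truth[("AxB", 2)] = (
            truth[("AxB", 2)], truth[("AxB", 1)],
        )
        swapped = _matrix_from_labels(triangle_design, swapped_truth)
        lab1 = assign_parent_labels(matrix, triangle_design)
        lab2 = assign_parent_labels(swapped, triangle_design)
        assert lab2.labels[("AxB", 1)] == lab1.labels[("AxB", 2)]
        assert lab2.labels[("AxB", 2)] == lab1.labels[("AxB", 1)]
        for key in lab1.labels:
            if key[0] != "AxB":
                assert lab2.labels[key] == lab1.labels[key]

    def test_genome_order_permutation_invariant(self, triangle_design):
        truth = {
            (g, h): sorted(triangle_design.pedigree[g])[h - 1]
            for g in triangle_design.genomes for h in (1, 2)
        }
        matrix = _matrix_from_labels(triangle_design, truth)
        base = assign_parent_labels(matrix, triangle_design)
        permuted = HybridDesign(
            genomes=("AxC", "AxB", "BxC"),
            pedigree=dict(triangle_design.pedigree),
        )
        assert assign_parent_labels(matrix, permuted).labels == base.labels


class TestBuildProfile:
    def test_clean_trio_votes_match_truth_labels(self, clean_trio, clean_tables):
        design = clean_trio.design
        for genome in design.genomes:
            for chrom in (1, 2):
                for hap in (1, 2):
                    profile = build_profile(
                        clean_trio.catalogs[genome], clean_tables[genome],
                        design, genome, chrom, hap,
                    )
                    expected = clean_trio.labels[(genome, chrom, hap)]
                    votes = [e.vote for e in profile.entries]
                    wrong = [v for v in votes if v not in (expected, AMBIGUOUS)]
                    assert not wrong
                    assert votes.count(expected) / len(votes) > 0.9

    def test_wrong_species_hit_votes_wrong_with_margin(self, triangle_design):
        table = BestHitTable()
        q = _locus("q_h1", chrom=1, hap=1)
        # genome AxB: spA via partner AxC, spB via partner BxC
        table.offer(_match(q, _locus("t1", hap=2), "AxC", 0.95))
        table.offer(_match(q, _locus("t2", hap=1), "BxC", 0.80))
        from triohap.io_formats import LocusCatalog

        catalog = LocusCatalog("AxB", [q])
        profile = build_profile(catalog, table, triangle_design, "AxB", 1, 1)
        (entry,) = profile.entries
        assert entry.vote == "spA"
        assert entry.margin == pytest.approx(0.15)

    def test_locus_without_hits_is_ambiguous(self, triangle_design):
        from triohap.io_formats import LocusCatalog

        catalog = LocusCatalog("AxB", [_locus("lonely_h1", hap=1)])
        profile = build_profile(
            catalog, BestHitTable(), triangle_design, "AxB", 1, 1
        )
        assert profile.entries[0].vote == AMBIGUOUS


def _profile(votes, margin=0.05, spacing=100, width=50):
    entries = [
        ProfileEntry(
            rank=i + 1, gene_id=f"g{i}", start=i * spacing,
            end=i * spacing + width, vote=v,
            margin=0.0 if v == AMBIGUOUS else margin,
        )
        for i, v in enumerate(votes)
    ]
    return AssignmentProfile(
        genome="AxB", chrom_index=1, haplotype=1,
        species_pair=("spA", "spB"), entries=entries,
    )


def _oracle_best_cut(votes, old, new):
    """Brute-force change-point: the cut maximizing flank purity."""
    best_cut, best_score = None, -1.0
    for cut in range(1, len(votes)):
        left = votes[:cut]
        right = votes[cut:]
        score = left.count(old) / len(left) + right.count(new) / len(right)
        if score > best_score:
            best_cut, best_score = cut, score
    return best_cut


class TestDetectSwitches:
    def test_uniform_profile_no_events(self):
        assert detect_switches(_profile(["spA"] * 50)) == []

    def test_single_change_point_between_loci_60_and_61(self):
        votes = ["spR"] * 60 + ["spB"] * 40
        events = detect_switches(_profile(votes), window=5, min_run=3)
        assert len(events) == 1
        (event,) = events
        # brute-force oracle agrees the cut is between loci 60 and 61
        assert _oracle_best_cut(votes, "spR", "spB") == 60
        assert event.breakpoint_interval == (59 * 100 + 50, 60 * 100)
        assert event.upstream_species == "spR"
        assert event.downstream_species == "spB"
        assert event.support_upstream == 60
        assert event.support_downstream == 40

    def test_isolated_wrong_votes_smoothed_away(self):
        votes = ["spA"] * 30 + ["spB"] + ["spA"] * 30
        assert detect_switches(_profile(votes)) == []

    def test_short_terminal_segment_respects_min_run(self):
        votes = ["spA"] * 40 + ["spB"] * 2
        assert detect_switches(_profile(votes), min_run=3) == []

    def test_two_state_changes_give_two_events(self):
        votes = ["spA"] * 30 + ["spB"] * 20 + ["spA"] * 30
        events = detect_switches(_profile(votes))
        assert [
            (e.upstream_species, e.downstream_species) for e in events
        ] == [("spA", "spB"), ("spB", "spA")]

    def test_mostly_ambiguous_profile_uncallable(self):
        votes = (["spA"] * 10 + [AMBIGUOUS] * 30) + ["spB"] * 10
        assert detect_switches(_profile(votes)) == []

    def test_terminal_segment_pattern_single_event(self):
        """First segment one species, terminal segment the other — the
        situation of a switch at the end of a chromosome."""
        votes = ["light_green"] * 150 + ["red"] * 33
        events = detect_switches(_profile(votes))
        assert len(events) == 1
        assert events[0].upstream_species == "light_green"
        assert events[0].downstream_species == "red"
        cut = _oracle_best_cut(votes, "light_green", "red")
        lo, hi = events[0].breakpoint_interval
        assert lo == (cut - 1) * 100 + 50 and hi == cut * 100


class TestPairSwitchEvents:
    def _event(self, hap, lo, hi, up, down):
        return SwitchEvent(
            genome="AxB", chrom_index=1, haplotype=hap,
            breakpoint_interval=(lo, hi), upstream_species=up,
            downstream_species=down, support_upstream=10, support_downstream=10,
        )

    def test_complementary_events_pair(self):
        e1 = self._event(1, 1000, 1200, "spA", "spB")
        e2 = self._event(2, 980, 1150, "spB", "spA")
        (paired,) = pair_switch_events([e1], [e2])
        assert paired.breakpoint_interval == (1000, 1150)

    def test_one_sided_event_dropped(self):
        e1 = self._event(1, 1000, 1200, "spA", "spB")
        assert pair_switch_events([e1], []) == []

    def test_non_complementary_states_do_not_pair(self):
        e1 = self._event(1, 1000, 1200, "spA", "spB")
        e2 = self._event(2, 1000, 1200, "spA", "spB")
        assert pair_switch_events([e1], [e2]) == []

    def test_distant_events_do_not_pair(self):
        e1 = self._event(1, 1000, 1200, "spA", "spB")
        e2 = self._event(2, 50_000, 50_200, "spB", "spA")
        assert pair_switch_events([e1], [e2], max_gap=10_000) == []

    def test_switched_trio_events_mirror_across_haplotypes(
        self, small_trio, small_tables
    ):
        """Genuine switches produce complementary change points on both
        haplotypes; every truth switch ends up in a pair."""
        design = small_trio.design
        n_paired = 0
        for genome in design.genomes:
            for chrom in (1, 2):
                events = {}
                for hap in (1, 2):
                    profile = build_profile(
                        small_trio.catalogs[genome], small_tables[genome],
                        design, genome, chrom, hap,
                    )
                    events[hap] = detect_switches(profile)
                paired = pair_switch_events(events[1], events[2])
                n_paired += len(paired)
                truth_here = [
                    t for t in small_trio.truth_switches
                    if t.genome == genome and t.chrom_index == chrom
                ]
                assert len(paired) == len(truth_here)
        assert n_paired == len(small_trio.truth_switches)
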