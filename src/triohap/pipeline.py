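"""End-to-end orchestration: simulate, score, assign, detect, correct,
compute divergence and colinearity statistics, and evaluate against truth.

Every stage is a plain function over in-memory objects so the pipeline is
equally usable from the CLI, from tests and from scripts; `run_full` wires
them together, writes all intermediates, and produces a deterministic
report for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import colinearity as colin
from . import correction as corr
from . import divergence as div
from . import parentage as par
from .io_formats import DiploidAssembly, LocusCatalog, write_outputs
from .similarity import BestHitTable, best_hits, extract_locus_sequences
from .synthetic import (
    AncestorModel,
    HybridDesign,
    SyntheticTrio,
    TruthSwitch,
    simulate_trio,
)

__all__ = [
    "RunConfig",
    "TruthEvaluation",
    "UncallableChromosomeError",
    "compute_best_hit_tables",
    "label_chromosomes",
    "detect_trio_switches",
    "evaluate_against_truth",
    "run_full",
]

logger = logging.getLogger(__name__)


class UncallableChromosomeError(RuntimeError):
    """Raised when a chromosome has too many ambiguous votes to call."""


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into the report."""

    model: AncestorModel = field(default_factory=AncestorModel)
    design: HybridDesign = field(default_factory=HybridDesign)
    switches_per_genome: int = 5
    haplotype_noise_scale: float = 0.2
    min_identity: float = 0.8
    min_coverage: float = 0.8
    vote_margin: float = par.VOTE_MARGIN
    label_margin: float = par.LABEL_MARGIN
    window: int = 5
    min_run: int = 3
    max_ambiguous_frac: float = 0.5
    pair_max_gap: int = 10_000
    snap_distance: int = corr.DEFAULT_SNAP_DISTANCE
    match_size: int = colin.MATCH_SIZE
    max_gap: int = colin.MAX_GAP
    overlap_window: int = colin.OVERLAP_WINDOW
    compute_divergence: bool = True
    compute_colinearity: bool = True
    permissive: bool = False
    out_dir: str | None = None
    force: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage floors must lie in [0, 1]")
        if self.window < 1 or self.min_run < 1:
            raise ValueError("window and min_run must be positive")
        if not (0 <= self.max_ambiguous_frac <= 1):
            raise ValueError("max_ambiguous_frac must lie in [0, 1]")
        self.design.validate()

    @property
    def seed(self) -> int:
        return self.model.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["pedigree"] = {
            g: sorted(sp) for g, sp in self.design.pedigree.items()
        }
        # run-location details are not part of the scientific provenance and
        # would break byte-determinism of reports across directories
        d.pop("out_dir", None)
        d.pop("force", None)
        return d


@dataclass
class TruthEvaluation:
    """Precision/recall of predicted switches against injected truth."""

    precision: float
    recall: float
    breakpoint_errors: list[int]
    n_predicted: int
    n_truth: int
    no_predictions_flag: bool = False

    @property
    def max_breakpoint_error(self) -> int:
        return max(self.breakpoint_errors) if self.breakpoint_errors else 0


def compute_best_hit_tables(
    assemblies: dict[str, DiploidAssembly],
    catalogs: dict[str, LocusCatalog],
    design: HybridDesign,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> dict[str, BestHitTable]:
    """Best-hit tables of every genome's loci against its two partners."""
    seqs = {
        g: extract_locus_sequences(assemblies[g], catalogs[g])
        for g in design.genomes
    }
    tables: dict[str, BestHitTable] = {}
    for genome in design.genomes:
        foreign = {
            other: (catalogs[other], seqs[other])
            for other in design.genomes
            if other != genome
        }
        tables[genome] = best_hits(
            catalogs[genome],
            seqs[genome],
            foreign,
            min_identity=min_identity,
            min_coverage=min_coverage,
        )
    return tables


def label_chromosomes(
    tables: dict[str, BestHitTable],
    design: HybridDesign,
    chromosomes,
    label_margin: float = par.LABEL_MARGIN,
) -> dict[int, par.ParentLabeling]:
    return {
        chrom: par.assign_parent_labels(
            par.build_similarity_matrix(tables, chrom), design,
            margin_threshold=label_margin,
        )
        for chrom in chromosomes
    }


def detect_trio_switches(
    catalogs: dict[str, LocusCatalog],
    tables: dict[str, BestHitTable],
    design: HybridDesign,
    chromosomes,
    vote_margin: float = par.VOTE_MARGIN,
    window: int = 5,
    min_run: int = 3,
    max_ambiguous_frac: float = 0.5,
    pair_max_gap: int = 10_000,
):
    """Profiles, per-haplotype events and paired chromosome-level switches.

    Returns ``(profiles, paired, uncallable)`` where ``profiles`` maps
    (genome, chrom, hap) to the assignment profile, ``paired`` maps genome
    to its paired switch calls and ``uncallable`` lists (genome, chrom,
    hap) triples whose vote signal was mostly ambiguous.
    """
    profiles: dict[tuple[str, int, int], par.AssignmentProfile] = {}
    paired: dict[str, list[par.PairedSwitch]] = {g: [] for g in design.genomes}
    uncallable: list[tuple[str, int, int]] = []
    for genome in design.genomes:
        for chrom in chromosomes:
            events = {}
            for hap in (1, 2):
                profile = par.build_profile(
                    catalogs[genome], tables[genome], design, genome, chrom, hap,
                    margin_threshold=vote_margin,
                )
                profiles[(genome, chrom, hap)] = profile
                if profile.ambiguous_fraction() > max_ambiguous_frac:
                    uncallable.append((genome, chrom, hap))
                    events[hap] = []
                else:
                    events[hap] = par.detect_switches(
                        profile, window=window, min_run=min_run,
                        max_ambiguous_frac=max_ambiguous_frac,
                    )
            paired[genome].extend(
                par.pair_switch_events(events[1], events[2], max_gap=pair_max_gap)
            )
    return profiles, paired, uncallable


def mean_intergenic_interval(catalog: LocusCatalog, chrom: int) -> int:
    loci = catalog.loci_of(chrom, 1)
    if not loci:
        return 10_000
    span = max(g.end for g in loci) - min(g.start for g in loci)
    return max(1, span // (len(loci) + 1))


def evaluate_against_truth(
    predicted: list[par.PairedSwitch],
    truth: list[TruthSwitch],
    tolerance_bp: int = 0,
) -> TruthEvaluation:
    """Greedy nearest matching of predicted switch intervals to truth points.

    A prediction matches a truth breakpoint when the breakpoint lies inside
    its interval or within ``tolerance_bp`` of it.  Unmatched predictions
    count against precision, unmatched truths against recall.
    """
    pairs = []
    for i, p in enumerate(predicted):
        lo, hi = p.breakpoint_interval
        for j, t in enumerate(truth):
            if p.genome != t.genome or p.chrom_index != t.chrom_index:
                continue
            if lo <= t.breakpoint <= hi:
                d = 0
            else:
                d = min(abs(t.breakpoint - lo), abs(t.breakpoint - hi))
            if d <= tolerance_bp:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    errors: list[int] = []
    for d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        errors.append(d)
    n_pred, n_truth = len(predicted), len(truth)
    if n_pred == 0:
        precision = 1.0 if n_truth == 0 else 0.0
        return TruthEvaluation(
            precision=precision,
            recall=1.0 if n_truth == 0 else 0.0,
            breakpoint_errors=[],
            n_predicted=0,
            n_truth=n_truth,
            no_predictions_flag=n_truth > 0,
        )
    return TruthEvaluation(
        precision=len(used_p) / n_pred,
        recall=len(used_t) / n_truth if n_truth else 1.0,
        breakpoint_errors=errors,
        n_predicted=n_pred,
        n_truth=n_truth,
    )


def _colinearity_stage(
    assemblies, catalogs, tables, labelings, design, config
):
    per_pair: list[dict] = []
    chroms = sorted(labelings)
    genome_pairs = [
        (a, b)
        for i, a in enumerate(design.genomes)
        for b in design.genomes[i + 1 :]
    ]
    for genome_a, genome_b in genome_pairs:
        for chrom in chroms:
            lab = labelings[chrom]
            for hap_a in (1, 2):
                for hap_b in (1, 2):
                    anchors = colin.build_anchors(
                        tables[genome_a], chrom, hap_a, genome_b, hap_b,
                        min_identity=config.min_identity,
                        min_coverage=config.min_coverage,
                    )
                    blocks = colin.chain_blocks(
                        anchors,
                        match_size=config.match_size,
                        max_gap=config.max_gap,
                        overlap_window=config.overlap_window,
                    )
                    n_a = len(catalogs[genome_a].loci_of(chrom, hap_a))
                    n_b = len(catalogs[genome_b].loci_of(chrom, hap_b))
                    len_a = len(assemblies[genome_a].sequence(chrom, hap_a))
                    len_b = len(assemblies[genome_b].sequence(chrom, hap_b))
                    locus_pct = colin.block_locus_coverage(blocks, n_a + n_b)
                    length_pct = (
                        colin.block_length_coverage(blocks, len_a, side="a")
                        + colin.block_length_coverage(blocks, len_b, side="b")
                    ) / 2
                    shared = lab.species_of(genome_a, hap_a) == lab.species_of(
                        genome_b, hap_b
                    )
                    per_pair.append(
                        {
                            "genome_a": genome_a,
                            "unit_a": f"chr{chrom}_hap{hap_a}",
                            "genome_b": genome_b,
                            "unit_b": f"chr{chrom}_hap{hap_b}",
                            "shared_species": shared,
                            "n_blocks": len(blocks),
                            "n_anchors": sum(b.n_anchors for b in blocks),
                            "locus_pct": locus_pct,
                            "length_pct": length_pct,
                        }
                    )
    return colin.coverage_stats(per_pair)


def run_full(config: RunConfig, trio: SyntheticTrio | None = None) -> dict:
    """Execute the full analysis and return the report dictionary.

    When ``trio`` is omitted a synthetic study is simulated from the
    config's model/design/seed.  Raises
    :class:`UncallableChromosomeError` if any chromosome is uncallable and
    the config is not permissive.
    """
    if trio is None:
        trio = simulate_trio(
            model=config.model,
            design=config.design,
            switches_per_genome=config.switches_per_genome,
            haplotype_noise_scale=config.haplotype_noise_scale,
        )
    design = config.design
    chroms = sorted(
        {c for asm in trio.assemblies.values() for c, _h in asm.chromosomes}
    )
    report: dict = {"config": config.to_dict(), "seed": config.seed}
    tables_dir: dict[str, pd.DataFrame] = {}

    logger.info("scoring gene loci across genomes")
    tables = compute_best_hit_tables(
        trio.assemblies, trio.catalogs, design,
        min_identity=config.min_identity, min_coverage=config.min_coverage,
    )
    for genome, table in tables.items():
        tables_dir[f"best_hits.{genome}"] = table.to_frame()

    labelings = label_chromosomes(
        tables, design, chroms, label_margin=config.label_margin
    )
    report["labeling"] = {
        str(chrom): {
            "labels": {f"{g}.hap{h}": sp for (g, h), sp in lab.labels.items()},
            "margin": lab.margin,
            "ambiguous": lab.ambiguous,
        }
        for chrom, lab in labelings.items()
    }

    logger.info("detecting haplotype switches")
    profiles, paired, uncallable = detect_trio_switches(
        trio.catalogs, tables, design, chroms,
        vote_margin=config.vote_margin, window=config.window,
        min_run=config.min_run, max_ambiguous_frac=config.max_ambiguous_frac,
        pair_max_gap=config.pair_max_gap,
    )
    if uncallable and not config.permissive:
        raise UncallableChromosomeError(
            f"uncallable chromosomes: {sorted(uncallable)}"
        )
    predicted = [p for g in design.genomes for p in paired[g]]
    report["switches"] = {
        "n_predicted": len(predicted),
        "per_genome": {g: len(paired[g]) for g in design.genomes},
        "uncallable": [list(u) for u in sorted(uncallable)],
    }
    for (genome, chrom, hap), profile in profiles.items():
        tables_dir[f"profile.{genome}.chr{chrom}.hap{hap}"] = profile.to_frame()

    if trio.truth_switches:
        tol = max(
            mean_intergenic_interval(trio.catalogs[g], c)
            for g in design.genomes
            for c in chroms
        )
        evaluation = evaluate_against_truth(
            predicted, trio.truth_switches, tolerance_bp=tol
        )
        report["switches"]["evaluation"] = {
            "precision": evaluation.precision,
            "recall": evaluation.recall,
            "n_truth": evaluation.n_truth,
            "tolerance_bp": tol,
            "max_breakpoint_error": evaluation.max_breakpoint_error,
        }

    logger.info("planning and applying corrections")
    corrected_asm: dict[str, DiploidAssembly] = {}
    corrected_cat: dict[str, LocusCatalog] = {}
    n_plans = dropped = 0
    plan_rows = []
    for genome in design.genomes:
        plans = corr.plan_correction(
            paired[genome], trio.assemblies[genome],
            snap_distance=config.snap_distance,
        )
        n_plans += len(plans)
        asm, cat, d = corr.apply_correction(
            trio.assemblies[genome], trio.catalogs[genome], plans
        )
        corrected_asm[genome] = asm
        corrected_cat[genome] = cat
        dropped += d
        for p in plans:
            plan_rows.append(
                {
                    "genome": p.genome, "chrom": p.chrom_index,
                    "cut_hap1": p.cut_hap1, "cut_hap2": p.cut_hap2,
                    "side": p.side,
                }
            )
    tables_dir["exchange_plans"] = pd.DataFrame(
        plan_rows, columns=["genome", "chrom", "cut_hap1", "cut_hap2", "side"]
    )
    report["correction"] = {"n_plans": n_plans, "dropped_loci": dropped}

    logger.info("re-scoring corrected assemblies")
    tables2 = compute_best_hit_tables(
        corrected_asm, corrected_cat, design,
        min_identity=config.min_identity, min_coverage=config.min_coverage,
    )
    labelings2 = label_chromosomes(
        tables2, design, chroms, label_margin=config.label_margin
    )
    _profiles2, paired2, _unc2 = detect_trio_switches(
        corrected_cat, tables2, design, chroms,
        vote_margin=config.vote_margin, window=config.window,
        min_run=config.min_run, max_ambiguous_frac=config.max_ambiguous_frac,
        pair_max_gap=config.pair_max_gap,
    )
    residual = sum(len(v) for v in paired2.values())
    report["correction"]["residual_events"] = residual

    if config.compute_divergence:
        logger.info("computing inter-haplotype divergence statistics")
        test, frame, _comps = div.grouped_similarity(
            corrected_asm, labelings2, design
        )
        tables_dir["haplotype_similarity"] = frame
        shared = test.shared_group
        nonshared = test.nonshared_group
        report["divergence"] = {
            "n_shared": len(shared),
            "n_nonshared": len(nonshared),
            "shared_mean_pct": sum(shared) / len(shared),
            "nonshared_mean_pct": sum(nonshared) / len(nonshared),
            "W": test.W,
            "p_value": test.p_value,
            "method": test.method,
        }

    if config.compute_colinearity:
        logger.info("computing colinearity coverage")
        frame, summary = _colinearity_stage(
            corrected_asm, corrected_cat, tables2, labelings2, design, config
        )
        tables_dir["colinearity"] = frame
        report["colinearity"] = summary

    if config.out_dir is not None:
        results = {
            "assemblies": [corrected_asm[g] for g in design.genomes],
            "catalogs": [corrected_cat[g] for g in design.genomes],
            "truth_switches": trio.truth_switches,
            "predicted_switches": predicted,
            "summary": report,
            "tables": tables_dir,
        }
        written = write_outputs(results, config.out_dir, force=config.force)
        report["written_files"] = written
        # summary.json was serialized before this key existed; rewrite it
        import json

        with open(Path(config.out_dir) / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
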