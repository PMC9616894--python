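"""Parental-species assignment and haplotype-switch detection.

For every chromosome, the six haploid units (three genomes x two
haplotypes) are compared through gene best-hit identities.  A labeling
assigns each unit to one of its genome's two pedigree species by maximizing
the summed similarity of the three shared-species unit pairs.  Along each
unit, every gene locus then votes for one of the two pedigree species, and
a haplotype switch appears as a change-point in that vote signal; because a
switch exchanges material between the two haplotypes of the same
chromosome, genuine switches produce complementary change-points on both
haplotypes, which is required before a switch is called.

Voting compares, for the genome under test, the best hit into each of the
two partner genomes (the maximum over that partner's two haplotypes).  The
per-position species content of a partner genome is invariant under its own
haplotype switches — a switch only moves material between its haplotypes —
so this vote is unaffected by phasing errors elsewhere in the trio.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import LocusCatalog
from .similarity import BestHitTable
from .synthetic import HybridDesign

__all__ = [
    "AMBIGUOUS",
    "HaplotypeSimilarityMatrix",
    "ParentLabeling",
    "ProfileEntry",
    "AssignmentProfile",
    "SwitchEvent",
    "PairedSwitch",
    "build_similarity_matrix",
    "assign_parent_labels",
    "build_profile",
    "detect_switches",
    "pair_switch_events",
]

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"

LOW_SUPPORT = 10
LABEL_MARGIN = 0.005
VOTE_MARGIN = 0.002


@dataclass
class HaplotypeSimilarityMatrix:
    """Mean best-hit identity between the six (genome, haplotype) units.

    Entries pool the identities of both query directions; ``support`` is
    the pooled locus count.  Entries with support below ``LOW_SUPPORT`` are
    flagged.
    """

    chrom_index: int
    units: list[tuple[str, int]]
    values: dict[tuple[tuple[str, int], tuple[str, int]], float] = field(
        default_factory=dict
    )
    support: dict[tuple[tuple[str, int], tuple[str, int]], int] = field(
        default_factory=dict
    )

    @staticmethod
    def _key(u, v):
        return (u, v) if u <= v else (v, u)

    def entry(self, u, v) -> float | None:
        return self.values.get(self._key(u, v))

    def support_of(self, u, v) -> int:
        return self.support.get(self._key(u, v), 0)

    def is_low_support(self, u, v) -> bool:
        return self.support_of(u, v) < LOW_SUPPORT

    def to_frame(self) -> pd.DataFrame:
        names = [f"{g}.hap{h}" for g, h in self.units]
        data = [
            [
                self.entry(u, v) if u != v else float("nan")
                for v in self.units
            ]
            for u in self.units
        ]
        return pd.DataFrame(data, index=names, columns=names)


def build_similarity_matrix(
    hit_tables: dict[str, BestHitTable], chrom_index: int
) -> HaplotypeSimilarityMatrix:
    """Pool per-locus best-hit identities into the 6x6 unit matrix.

    ``hit_tables`` maps each genome name to the best-hit table of its loci
    against the other genomes.  Entry (u, v) is the mean identity over hits
    from u's loci into v and from v's loci into u.
    """
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    units: set[tuple[str, int]] = set()
    for genome, table in hit_tables.items():
        for match in table:
            if match.query.chrom_index != chrom_index:
                continue
            if match.target.chrom_index != chrom_index:
                continue
            u = (genome, match.query.haplotype)
            v = match.target_unit
            units.add(u)
            units.add(v)
            key = HaplotypeSimilarityMatrix._key(u, v)
            sums[key] = sums.get(key, 0.0) + match.identity
            counts[key] = counts.get(key, 0) + 1
    matrix = HaplotypeSimilarityMatrix(
        chrom_index=chrom_index, units=sorted(units)
    )
    for key, total in sums.items():
        matrix.values[key] = total / counts[key]
        matrix.support[key] = counts[key]
    return matrix


@dataclass
class ParentLabeling:
    """Per-chromosome assignment of each haplotype to a parental species."""

    chrom_index: int
    labels: dict[tuple[str, int], str]
    margin: float
    ambiguous: bool = False
    provisional: bool = False

    @property
    def assigned(self) -> bool:
        return not self.ambiguous

    def species_of(self, genome: str, haplotype: int) -> str:
        return self.labels[(genome, haplotype)]

    def unit_labeled(self, genome: str, species: str) -> tuple[str, int]:
        for hap in (1, 2):
            if self.labels.get((genome, hap)) == species:
                return genome, hap
        raise KeyError(f"no haplotype of {genome} labeled {species}")


def assign_parent_labels(
    matrix: HaplotypeSimilarityMatrix,
    design: HybridDesign,
    margin_threshold: float = LABEL_MARGIN,
) -> ParentLabeling:
    """Exhaustive search over the 2^3 per-genome haplotype orientations.

    The labeling maximizing the sum of the three shared-species matrix
    entries wins; a margin below ``margin_threshold`` over the runner-up
    flags the chromosome ambiguous (labels are still reported as the
    provisional argmax).  Missing or low-support entries make the labeling
    provisional.
    """
    genomes = list(design.genomes)
    pairs = list(itertools.combinations(genomes, 2))
    provisional = False
    scored: list[tuple[float, dict[tuple[str, int], str]]] = []
    for bits in itertools.product((0, 1), repeat=3):
        labels: dict[tuple[str, int], str] = {}
        for genome, bit in zip(genomes, bits):
            a, b = sorted(design.pedigree[genome])
            labels[(genome, 1)] = a if bit == 0 else b
            labels[(genome, 2)] = b if bit == 0 else a
        score = 0.0
        for g1, g2 in pairs:
            sp = design.shared_species(g1, g2)
            u = next(k for k, v in labels.items() if k[0] == g1 and v == sp)
            v = next(k for k, s in labels.items() if k[0] == g2 and s == sp)
            entry = matrix.entry(u, v)
            if entry is None:
                provisional = True
                entry = 0.0
            elif matrix.is_low_support(u, v):
                provisional = True
            score += entry
        scored.append((score, labels))
    scored.sort(key=lambda t: t[0], reverse=True)
    best_score, best_labels = scored[0]
    margin = best_score - scored[1][0]
    ambiguous = margin < margin_threshold
    if ambiguous:
        logger.info(
            "chromosome %d: parent labeling ambiguous (margin %.4f)",
            matrix.chrom_index, margin,
        )
    return ParentLabeling(
        chrom_index=matrix.chrom_index,
        labels=best_labels,
        margin=margin,
        ambiguous=ambiguous,
        provisional=provisional,
    )


@dataclass
class ProfileEntry:
    rank: int
    gene_id: str
    start: int
    end: int
    vote: str
    margin: float


@dataclass
class AssignmentProfile:
    """Ordered per-locus parental votes along one haplotype."""

    genome: str
    chrom_index: int
    haplotype: int
    species_pair: tuple[str, str]
    entries: list[ProfileEntry] = field(default_factory=list)

    def ambiguous_fraction(self) -> float:
        if not self.entries:
            return 1.0
        return sum(1 for e in self.entries if e.vote == AMBIGUOUS) / len(self.entries)

    def votes(self) -> list[str]:
        return [e.vote for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": e.rank, "gene_id": e.gene_id, "start": e.start,
                    "end": e.end, "vote": e.vote, "margin": e.margin,
                }
                for e in self.entries
            ],
            columns=["rank", "gene_id", "start", "end", "vote", "margin"],
        )


def build_profile(
    catalog: LocusCatalog,
    hits: BestHitTable,
    design: HybridDesign,
    genome: str,
    chrom_index: int,
    haplotype: int,
    margin_threshold: float = VOTE_MARGIN,
    missing_floor: float = 0.8,
) -> AssignmentProfile:
    """Per-locus species votes for one haplotype of one chromosome.

    Each locus compares its best hit into the partner genome sharing
    species X (maximum identity over that partner's two haplotypes) with
    its best hit into the partner sharing species Y.  The higher identity
    wins the vote; margins below ``margin_threshold`` (or loci without any
    hit) vote ``ambiguous``.  A missing competitor is scored at
    ``missing_floor``, the best-hit identity floor it must have fallen
    under.
    """
    sp_x, sp_y = sorted(design.pedigree[genome])
    partner_x = design.partner_sharing(genome, sp_x)
    partner_y = design.partner_sharing(genome, sp_y)
    profile = AssignmentProfile(
        genome=genome,
        chrom_index=chrom_index,
        haplotype=haplotype,
        species_pair=(sp_x, sp_y),
    )
    for locus in catalog.loci_of(chrom_index, haplotype):
        best: dict[str, float | None] = {}
        for sp, partner in ((sp_x, partner_x), (sp_y, partner_y)):
            ids = [
                m.identity
                for hap in (1, 2)
                if (m := hits.get(locus.gene_id, (partner, hap))) is not None
                and m.target.chrom_index == chrom_index
            ]
            best[sp] = max(ids) if ids else None
        if best[sp_x] is None and best[sp_y] is None:
            vote, margin = AMBIGUOUS, 0.0
        else:
            id_x = best[sp_x] if best[sp_x] is not None else missing_floor
            id_y = best[sp_y] if best[sp_y] is not None else missing_floor
            margin = abs(id_x - id_y)
            if margin < margin_threshold:
                vote = AMBIGUOUS
            else:
                vote = sp_x if id_x > id_y else sp_y
        profile.entries.append(
            ProfileEntry(
                rank=locus.rank,
                gene_id=locus.gene_id,
                start=locus.start,
                end=locus.end,
                vote=vote,
                margin=margin,
            )
        )
    return profile


@dataclass
class SwitchEvent:
    """A change-point in the assignment signal of one haplotype."""

    genome: str
    chrom_index: int
    haplotype: int
    breakpoint_interval: tuple[int, int]
    upstream_species: str
    downstream_species: str
    support_upstream: int
    support_downstream: int


def _smooth_votes(votes: list[str], window: int) -> list[str | None]:
    half = window // 2
    smoothed: list[str | None] = []
    for i in range(len(votes)):
        counts: dict[str, int] = {}
        for v in votes[max(0, i - half) : i + half + 1]:
            if v != AMBIGUOUS:
                counts[v] = counts.get(v, 0) + 1
        if not counts:
            smoothed.append(None)
            continue
        ranked = sorted(counts.items(), key=lambda kv: kv[1], reverse=True)
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            smoothed.append(None)
        else:
            smoothed.append(ranked[0][0])
    return smoothed


def detect_switches(
    profile: AssignmentProfile,
    window: int = 5,
    min_run: int = 3,
    max_ambiguous_frac: float = 0.5,
) -> list[SwitchEvent]:
    """Change-point scan over smoothed per-locus votes.

    Votes are majority-smoothed over sliding windows of ``window`` loci; a
    state change is committed when at least ``min_run`` consecutive smoothed
    votes support the new state.  The breakpoint interval runs from the end
    of the last raw-vote locus of the old state to the start of the first
    raw-vote locus of the new state.  Events with fewer than ``min_run``
    supporting raw votes on either flank are suppressed.  A profile with
    more than ``max_ambiguous_frac`` ambiguous votes is uncallable: it is
    logged and no events are returned.
    """
    entries = profile.entries
    if not entries:
        return []
    if profile.ambiguous_fraction() > max_ambiguous_frac:
        logger.warning(
            "%s chr%d hap%d: %.0f%% ambiguous votes, chromosome uncallable",
            profile.genome, profile.chrom_index, profile.haplotype,
            100 * profile.ambiguous_fraction(),
        )
        return []
    votes = profile.votes()
    smoothed = _smooth_votes(votes, window)

    # segment the smoothed signal with the min_run persistence rule
    segments: list[tuple[str, int, int]] = []  # (state, first_idx, last_idx)
    state: str | None = None
    pending: str | None = None
    pending_start = 0
    pending_len = 0
    seg_start = 0
    for i, s in enumerate(smoothed):
        if s is None:
            continue
        if state is None:
            state = s
            seg_start = i
            continue
        if s == state:
            pending = None
            pending_len = 0
            continue
        if s == pending:
            pending_len += 1
        else:
            pending = s
            pending_start = i
            pending_len = 1
        if pending_len >= min_run:
            segments.append((state, seg_start, pending_start - 1))
            state = pending
            seg_start = pending_start
            pending = None
            pending_len = 0
    if state is not None:
        segments.append((state, seg_start, len(smoothed) - 1))

    events: list[SwitchEvent] = []
    for (old, old_lo, old_hi), (new, new_lo, new_hi) in zip(segments, segments[1:]):
        j = next(
            (i for i in range(new_lo, new_hi + 1) if votes[i] == new), None
        )
        i = next(
            (t for t in range((j if j is not None else new_lo) - 1, -1, -1)
             if votes[t] == old),
            None,
        )
        if i is None or j is None:
            continue
        support_up = sum(1 for t in range(old_lo, old_hi + 1) if votes[t] == old)
        support_down = sum(1 for t in range(new_lo, new_hi + 1) if votes[t] == new)
        if support_up < min_run or support_down < min_run:
            continue
        events.append(
            SwitchEvent(
                genome=profile.genome,
                chrom_index=profile.chrom_index,
                haplotype=profile.haplotype,
                breakpoint_interval=(entries[i].end, entries[j].start),
                upstream_species=old,
                downstream_species=new,
                support_upstream=support_up,
                support_downstream=support_down,
            )
        )
    return events


@dataclass
class PairedSwitch:
    """A chromosome-level switch call supported by both haplotypes."""

    genome: str
    chrom_index: int
    interval_hap1: tuple[int, int]
    interval_hap2: tuple[int, int]
    upstream_species_hap1: str
    downstream_species_hap1: str

    @property
    def upstream_species(self) -> str:
        return self.upstream_species_hap1

    @property
    def downstream_species(self) -> str:
        return self.downstream_species_hap1

    @property
    def breakpoint_interval(self) -> tuple[int, int]:
        lo = max(self.interval_hap1[0], self.interval_hap2[0])
        hi = min(self.interval_hap1[1], self.interval_hap2[1])
        if lo <= hi:
            return lo, hi
        return (
            min(self.interval_hap1[0], self.interval_hap2[0]),
            max(self.interval_hap1[1], self.interval_hap2[1]),
        )


def pair_switch_events(
    events_hap1: list[SwitchEvent],
    events_hap2: list[SwitchEvent],
    max_gap: int = 10_000,
) -> list[PairedSwitch]:
    """Keep only complementary event pairs across the two haplotypes.

    A genuine switch exchanges material between the haplotypes, so its
    change-points appear on both, with mirrored species states, at nearly
    the same position.  Events lacking a complementary partner within
    ``max_gap`` bp are distortions induced elsewhere (e.g. by a phasing
    error in a partner genome) and are dropped.
    """

    def _mid(iv: tuple[int, int]) -> float:
        return (iv[0] + iv[1]) / 2

    used2: set[int] = set()
    paired: list[PairedSwitch] = []
    for e1 in sorted(events_hap1, key=lambda e: e.breakpoint_interval):
        best_j, best_d = None, None
        for j, e2 in enumerate(events_hap2):
            if j in used2:
                continue
            if (
                e1.upstream_species != e2.downstream_species
                or e1.downstream_species != e2.upstream_species
            ):
                continue
            d = abs(_mid(e1.breakpoint_interval) - _mid(e2.breakpoint_interval))
            if d <= max_gap and (best_d is None or d < best_d):
                best_j, best_d = j, d
        if best_j is not None:
            used2.add(best_j)
            e2 = events_hap2[best_j]
            paired.append(
                PairedSwitch(
                    genome=e1.genome,
                    chrom_index=e1.chrom_index,
                    interval_hap1=e1.breakpoint_interval,
                    interval_hap2=e2.breakpoint_interval,
                    upstream_species_hap1=e1.upstream_species,
                    downstream_species_hap1=e1.downstream_species,
                )
            )
    paired.sort(key=lambda p: (p.chrom_index, p.breakpoint_interval))
    return paired
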