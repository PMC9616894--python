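"""Synthetic trios of hybrid diploid assemblies with machine-readable truth.

The generator emulates the shared-parentage situation of three interspecific
hybrids: three parental species genomes (one ancestral, two derived from it
by independent mutation passes at different rates, giving three distinct
pairwise divergence levels), three hybrid genomes whose haplotypes are
lightly re-mutated copies of their two parental species, contig composition
as AGP components, and injected haplotype switches that exchange the
sequence on one side of a breakpoint between the two haplotypes of a
chromosome.

Divergence classes realized: SNPs, short indels (<= 50 bp) and structural
variants (> 50 bp; deletions and tandem duplications).  Gene loci are lifted
through every edit so orthologs correspond across species and haplotypes.

One integer seed drives a single numpy Generator threaded through all
sampling; identical seeds give byte-identical output.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import _BASE_CODE
from .correction import exchange_segments
from .io_formats import (
    AgpComponent,
    DiploidAssembly,
    GeneLocus,
    LocusCatalog,
    SeqRecord,
    format_seq_id,
)

__all__ = [
    "AncestorModel",
    "HybridDesign",
    "TruthSwitch",
    "AncestorSet",
    "SyntheticTrio",
    "MutationResult",
    "EditPlan",
    "mutate_sequence",
    "simulate_ancestors",
    "compose_hybrids",
    "inject_switches",
    "simulate_trio",
    "ortholog_id",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SPECIES = ("spA", "spB", "spC")


def ortholog_id(gene_id: str) -> str:
    """Ortholog identifier shared across species/haplotypes for a gene id."""
    return gene_id.split("_h")[0]


@dataclass
class AncestorModel:
    """Parameters of the three-species divergence model.

    ``snp_rate`` and ``indel_rate`` are per-bp probabilities between sister
    species; ``species_scales`` multiply them for the second and third
    species' mutation passes so the three pairwise divergences differ.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes_per_chrom: int = 200
    gene_length: int = 1_000
    snp_rate: float = 0.02
    indel_rate: float = 0.004
    indel_max: int = 10
    sv_count_per_chrom: int = 5
    sv_length_range: tuple[int, int] = (100, 2_000)
    seed: int = 0
    species_scales: tuple[float, float] = (1.0, 1.5)

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate <= 0.2 and 0 <= self.indel_rate <= 0.2):
            raise ValueError("mutation rates must lie in [0, 0.2]")
        if not (self.indel_max <= 50 < self.sv_length_range[0]):
            raise ValueError("need indel_max <= 50 < min SV length")
        if self.sv_length_range[0] > self.sv_length_range[1]:
            raise ValueError("bad sv_length_range")
        if self.gene_length < 1 or self.n_genes_per_chrom < 0:
            raise ValueError("bad gene parameters")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class HybridDesign:
    """Three hybrid genomes forming a triangle over three parental species.

    Each genome is the cross of two species and each species appears in
    exactly two genomes, so every pair of genomes shares exactly one
    parental species.
    """

    genomes: tuple[str, str, str] = ("AxB", "BxC", "AxC")
    pedigree: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pedigree:
            a, b, c = DEFAULT_SPECIES
            self.pedigree = {
                self.genomes[0]: frozenset((a, b)),
                self.genomes[1]: frozenset((b, c)),
                self.genomes[2]: frozenset((a, c)),
            }
        self.validate()

    def validate(self) -> None:
        if len(set(self.genomes)) != 3 or set(self.pedigree) != set(self.genomes):
            raise ValueError("pedigree must cover exactly the three genomes")
        counts: dict[str, int] = {}
        for pair in self.pedigree.values():
            if len(pair) != 2:
                raise ValueError("each genome must be a cross of two species")
            for sp in pair:
                counts[sp] = counts.get(sp, 0) + 1
        if len(counts) != 3 or set(counts.values()) != {2}:
            raise ValueError(
                "pedigree is not a triangle: need three species, each in "
                "exactly two genomes"
            )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({sp for pair in self.pedigree.values() for sp in pair}))

    def shared_species(self, genome_a: str, genome_b: str) -> str:
        common = self.pedigree[genome_a] & self.pedigree[genome_b]
        if len(common) != 1:
            raise ValueError(f"{genome_a} and {genome_b} do not share one species")
        return next(iter(common))

    def partner_sharing(self, genome: str, species: str) -> str:
        """The other genome that carries ``species``."""
        for other in self.genomes:
            if other != genome and species in self.pedigree[other]:
                return other
        raise ValueError(f"no other genome carries {species!r}")


@dataclass
class TruthSwitch:
    """An injected haplotype switch: ground truth for detection."""

    genome: str
    chrom_index: int
    breakpoint: int
    segment: str = "right"


# ---------------------------------------------------------------------------
# Edit plans: apply mutations and lift coordinates through them
# ---------------------------------------------------------------------------


class EditPlan:
    """An ordered, non-overlapping set of edits on one source sequence.

    Edits are tuples: ``('snp', pos, base)``, ``('del', start, length)``,
    ``('ins', pos, seq)`` (insertion before ``pos``; tandem duplications are
    realized as insertions).  Positions are source coordinates.
    """

    def __init__(self, edits):
        self.edits = sorted(edits, key=lambda e: (e[1], 0 if e[0] == "ins" else 1))
        self._ins_pos = np.array(
            [e[1] for e in self.edits if e[0] == "ins"], dtype=np.int64
        )
        self._ins_cum = np.cumsum(
            [len(e[2]) for e in self.edits if e[0] == "ins"]
        ).astype(np.int64) if self._ins_pos.size else np.empty(0, np.int64)
        dels = [e for e in self.edits if e[0] == "del"]
        self._del_start = np.array([e[1] for e in dels], dtype=np.int64)
        self._del_end = np.array([e[1] + e[2] for e in dels], dtype=np.int64)
        self._del_cum = np.cumsum([e[2] for e in dels]).astype(np.int64) if dels \
            else np.empty(0, np.int64)

    def apply(self, seq: str) -> str:
        pieces: list[str] = []
        cur = 0
        for edit in self.edits:
            kind = edit[0]
            if kind == "snp":
                _, pos, base = edit
                pieces.append(seq[cur:pos])
                pieces.append(base)
                cur = pos + 1
            elif kind == "del":
                _, start, length = edit
                pieces.append(seq[cur:start])
                cur = start + length
            else:
                _, pos, ins = edit
                pieces.append(seq[cur:pos])
                pieces.append(ins)
                cur = pos
        pieces.append(seq[cur:])
        return "".join(pieces)

    def lift(self, pos: int) -> int:
        """Map a source boundary position into derived coordinates.

        Positions inside a deleted span collapse onto the deletion start.
        """
        i = int(np.searchsorted(self._del_start, pos, side="right")) - 1
        if i >= 0 and pos < self._del_end[i]:
            pos = int(self._del_start[i])
        ins_shift = int(
            self._ins_cum[np.searchsorted(self._ins_pos, pos, side="left") - 1]
        ) if np.searchsorted(self._ins_pos, pos, side="left") > 0 else 0
        j = int(np.searchsorted(self._del_end, pos, side="right")) - 1
        del_shift = int(self._del_cum[j]) if j >= 0 else 0
        return pos + ins_shift - del_shift

    def lift_interval(self, start: int, end: int) -> tuple[int, int]:
        return self.lift(start), self.lift(end)

    def counts(self) -> dict[str, int]:
        out = {"snp": 0, "del": 0, "ins": 0}
        for e in self.edits:
            out[e[0]] += 1
        return out


@dataclass
class MutationResult:
    sequence: str
    plan: EditPlan

    @property
    def snp_count(self) -> int:
        return self.plan.counts()["snp"]


def _overlaps(occupied: list[tuple[int, int]], start: int, end: int) -> bool:
    i = bisect.bisect_left(occupied, (start, start))
    if i > 0 and occupied[i - 1][1] > start:
        return True
    return i < len(occupied) and occupied[i][0] < end


def _crosses_boundary(boundaries: np.ndarray, start: int, end: int) -> bool:
    lo = np.searchsorted(boundaries, start, side="right")
    hi = np.searchsorted(boundaries, end, side="left")
    return bool(hi > lo)


def mutate_sequence(
    rng: np.random.Generator,
    seq: str,
    gene_spans: list[tuple[int, int]],
    snp_rate: float,
    indel_rate: float,
    indel_max: int = 10,
    sv_count: int = 0,
    sv_length_range: tuple[int, int] = (100, 2_000),
) -> MutationResult:
    """One mutation pass over a sequence, honouring gene-locus structure.

    SNPs land anywhere (not inside deletions); short indels must not cross a
    gene boundary (fully genic or fully intergenic); SV deletions and tandem
    duplications are placed entirely in intergenic space so every ortholog
    survives the pass.
    """
    length = len(seq)
    gene_spans = sorted(gene_spans)
    boundaries = np.array(
        [b for span in gene_spans for b in span], dtype=np.int64
    )
    occupied: list[tuple[int, int]] = []
    edits: list[tuple] = []

    # intergenic intervals
    intergenic: list[tuple[int, int]] = []
    pos = 0
    for s, e in gene_spans:
        if s > pos:
            intergenic.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        intergenic.append((pos, length))

    # structural variants
    lo, hi = sv_length_range
    for _ in range(sv_count):
        sv_len = int(rng.integers(lo, hi + 1))
        eligible = [iv for iv in intergenic if iv[1] - iv[0] >= sv_len + 2]
        placed = False
        for _try in range(20):
            if not eligible:
                break
            iv = eligible[int(rng.integers(len(eligible)))]
            start = int(rng.integers(iv[0] + 1, iv[1] - sv_len))
            if _overlaps(occupied, start, start + sv_len):
                continue
            if rng.random() < 0.5:
                edits.append(("del", start, sv_len))
            else:
                edits.append(("ins", start + sv_len, seq[start : start + sv_len]))
            bisect.insort(occupied, (start, start + sv_len))
            placed = True
            break
        if not placed:
            logger.info("could not place a %d bp SV; skipped", sv_len)

    # short indels
    n_indels = int(rng.binomial(length, indel_rate)) if indel_rate > 0 else 0
    for _ in range(n_indels):
        ind_len = int(rng.integers(1, indel_max + 1))
        for _try in range(8):
            start = int(rng.integers(1, length - ind_len - 1))
            if _overlaps(occupied, start, start + ind_len):
                continue
            if rng.random() < 0.5:
                if _crosses_boundary(boundaries, start, start + ind_len):
                    continue
                edits.append(("del", start, ind_len))
                bisect.insort(occupied, (start, start + ind_len))
            else:
                if np.any(boundaries == start):
                    continue
                ins = "".join(
                    chr(_BASES[i]) for i in rng.integers(0, 4, ind_len)
                )
                edits.append(("ins", start, ins))
                bisect.insort(occupied, (start, start + 1))
            break

    # SNPs
    if snp_rate > 0:
        snp_pos = np.flatnonzero(rng.random(length) < snp_rate)
        codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
        snp_pos = snp_pos[codes[snp_pos] >= 0]
        if occupied:
            occ_start = np.array([s for s, _ in occupied], dtype=np.int64)
            occ_end = np.array([e for _, e in occupied], dtype=np.int64)
            idx = np.searchsorted(occ_start, snp_pos, side="right") - 1
            inside = (idx >= 0) & (snp_pos < occ_end[np.clip(idx, 0, None)])
            snp_pos = snp_pos[~inside]
        offsets = rng.integers(1, 4, snp_pos.size)
        new_codes = (codes[snp_pos] + offsets) % 4
        for p, c in zip(snp_pos.tolist(), new_codes.tolist()):
            edits.append(("snp", int(p), chr(_BASES[c])))

    plan = EditPlan(edits)
    return MutationResult(sequence=plan.apply(seq), plan=plan)


# ---------------------------------------------------------------------------
# Ancestors
# ---------------------------------------------------------------------------


@dataclass
class AncestorSet:
    """Three haploid species genomes with orthologous gene catalogs."""

    species: tuple[str, str, str]
    sequences: dict[str, dict[int, str]]
    catalogs: dict[str, LocusCatalog]
    plans: dict[str, dict[int, EditPlan]]
    model: AncestorModel

    def snp_count(self, species: str) -> int:
        """Realized SNP count of one derived species' mutation pass."""
        return sum(p.counts()["snp"] for p in self.plans[species].values())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def simulate_ancestors(
    model: AncestorModel,
    rng: np.random.Generator | None = None,
    species: tuple[str, str, str] = DEFAULT_SPECIES,
) -> AncestorSet:
    """Simulate the three parental species genomes.

    The first species is drawn uniformly; the second and third derive from
    it by independent mutation passes at ``model`` rates scaled by
    ``model.species_scales``, so the three pairwise divergences are
    distinct.  Gene loci are lifted through all edits.
    """
    if rng is None:
        rng = model.rng()
    K, L = model.n_chromosomes, model.chrom_length
    n, glen = model.n_genes_per_chrom, model.gene_length
    slack = L - n * (glen + 2) - 2
    if slack <= 0:
        raise ValueError(
            f"gene placement infeasible: {n} genes of {glen} bp do not fit "
            f"in {L} bp"
        )

    base_name = species[0]
    sequences: dict[str, dict[int, str]] = {sp: {} for sp in species}
    plans: dict[str, dict[int, EditPlan]] = {sp: {} for sp in species}
    gene_table: dict[int, list[tuple[str, int, int, str]]] = {}

    for chrom in range(1, K + 1):
        seq = _random_sequence(rng, L)
        sequences[base_name][chrom] = seq
        raw = np.sort(rng.choice(slack, size=n, replace=False))
        starts = raw + np.arange(n) * (glen + 2) + 1
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        gene_table[chrom] = [
            (
                f"c{chrom:02d}g{i:04d}",
                int(s),
                int(s) + glen,
                str(strands[i]),
            )
            for i, s in enumerate(starts)
        ]

    def _catalog(sp: str, lift=None) -> LocusCatalog:
        loci = []
        for chrom, genes in gene_table.items():
            plan = plans[sp].get(chrom)
            for gid, s, e, strand in genes:
                if plan is not None:
                    s, e = plan.lift_interval(s, e)
                loci.append(
                    GeneLocus(
                        gene_id=gid, chrom_index=chrom, haplotype=1,
                        start=s, end=e, strand=strand,
                    )
                )
        return LocusCatalog(sp, loci)

    for sp, scale in zip(species[1:], model.species_scales):
        for chrom in range(1, K + 1):
            spans = [(s, e) for _g, s, e, _st in gene_table[chrom]]
            res = mutate_sequence(
                rng,
                sequences[base_name][chrom],
                spans,
                snp_rate=model.snp_rate * scale,
                indel_rate=model.indel_rate * scale,
                indel_max=model.indel_max,
                sv_count=model.sv_count_per_chrom,
                sv_length_range=model.sv_length_range,
            )
            sequences[sp][chrom] = res.sequence
            plans[sp][chrom] = res.plan

    catalogs = {sp: _catalog(sp) for sp in species}
    return AncestorSet(
        species=species, sequences=sequences, catalogs=catalogs,
        plans=plans, model=model,
    )


# ---------------------------------------------------------------------------
# Hybrids
# ---------------------------------------------------------------------------


def compose_hybrids(
    ancestors: AncestorSet,
    design: HybridDesign,
    rng: np.random.Generator | None = None,
    haplotype_noise_scale: float = 0.2,
    components_range: tuple[int, int] = (2, 6),
    n_unplaced: int = 2,
    unplaced_length: int = 5_000,
):
    """Compose the three hybrid genomes from the parental species.

    Each haplotype is a fresh mutated copy of one parental species sequence
    at ``haplotype_noise_scale`` times the between-species rates (SNPs and
    short indels only), so haplotypes sharing a species stay far more
    similar than haplotypes of different species.  Which species lands on
    haplotype 1 is randomized per chromosome.  Contig composition is
    generated by cutting each pseudomolecule into 2-6 components.

    Returns ``(assemblies, catalogs, labels)`` where ``labels`` maps
    ``(genome, chrom, haplotype) -> species`` (the pre-injection truth).
    """
    design.validate()
    if set(design.species) != set(ancestors.species):
        raise ValueError("design species do not match the simulated ancestors")
    if rng is None:
        rng = ancestors.model.rng()
    model = ancestors.model
    assemblies: dict[str, DiploidAssembly] = {}
    catalogs: dict[str, LocusCatalog] = {}
    labels: dict[tuple[str, int, int], str] = {}

    for genome in design.genomes:
        pair = sorted(design.pedigree[genome])
        chromosomes: dict[tuple[int, int], SeqRecord] = {}
        components: list[AgpComponent] = []
        loci: list[GeneLocus] = []
        tig_counter = 0
        for chrom in range(1, model.n_chromosomes + 1):
            order = list(pair) if rng.random() < 0.5 else list(reversed(pair))
            for hap, sp in enumerate(order, start=1):
                src = ancestors.sequences[sp][chrom]
                src_cat = ancestors.catalogs[sp]
                spans = [
                    (g.start, g.end) for g in src_cat.loci_of(chrom, 1)
                ]
                res = mutate_sequence(
                    rng,
                    src,
                    spans,
                    snp_rate=model.snp_rate * haplotype_noise_scale,
                    indel_rate=model.indel_rate * haplotype_noise_scale,
                    indel_max=model.indel_max,
                    sv_count=0,
                )
                seq_id = format_seq_id(chrom, hap)
                chromosomes[(chrom, hap)] = SeqRecord(id=seq_id, sequence=res.sequence)
                labels[(genome, chrom, hap)] = sp
                for g in src_cat.loci_of(chrom, 1):
                    s, e = res.plan.lift_interval(g.start, g.end)
                    loci.append(
                        GeneLocus(
                            gene_id=f"{g.gene_id}_h{hap}",
                            chrom_index=chrom,
                            haplotype=hap,
                            start=s,
                            end=e,
                            strand=g.strand,
                        )
                    )
                # contig composition
                n_comp = int(rng.integers(components_range[0], components_range[1] + 1))
                length = len(res.sequence)
                cuts = np.sort(
                    rng.choice(length - 2, size=n_comp - 1, replace=False) + 1
                )
                edges = [0, *cuts.tolist(), length]
                for a, b in zip(edges, edges[1:]):
                    components.append(
                        AgpComponent(
                            object_id=seq_id,
                            object_start=a,
                            object_end=b,
                            component_id=f"{genome}_h{hap}tg{tig_counter:06d}l",
                        )
                    )
                    tig_counter += 1
        unplaced = [
            SeqRecord(
                id=f"{genome}_utg{i:04d}l",
                sequence=_random_sequence(rng, unplaced_length),
            )
            for i in range(n_unplaced)
        ]
        asm = DiploidAssembly(
            genome_name=genome,
            chromosomes=chromosomes,
            unplaced=unplaced,
            components=components,
        )
        asm.validate()
        assemblies[genome] = asm
        catalogs[genome] = LocusCatalog(genome, loci)
    return assemblies, catalogs, labels


# ---------------------------------------------------------------------------
# Switch injection
# ---------------------------------------------------------------------------


def _is_intergenic(catalog: LocusCatalog, chrom: int, pos: int) -> bool:
    for hap in (1, 2):
        for g in catalog.loci_of(chrom, hap):
            if g.start < pos < g.end:
                return False
    return True


def inject_switches(
    assembly: DiploidAssembly,
    catalog: LocusCatalog,
    k: int,
    rng: np.random.Generator,
    junction_prob: float = 0.8,
    min_separation: int | None = None,
):
    """Inject ``k`` haplotype switches into one assembly; truth is returned.

    Breakpoints are sampled from AGP component junctions with probability
    ``junction_prob``, otherwise uniformly in the chromosome interior; a
    breakpoint must be intergenic on both haplotypes and at least
    ``min_separation`` (default: eight mean gene intervals, so every
    exchanged segment carries enough gene votes to be resolvable) from
    previously placed breakpoints and the chromosome ends, else it is
    resampled.

    Returns ``(assembly, catalog, truth)`` with fresh objects; the inputs
    are untouched.  Injection is an involution: re-exchanging at the same
    breakpoints restores the input.
    """
    if k == 0:
        return assembly, catalog, []
    chroms = sorted({c for c, _h in assembly.chromosomes})
    placed: dict[int, list[int]] = {c: [] for c in chroms}
    truth: list[TruthSwitch] = []
    for _ in range(k):
        chrom = int(chroms[int(rng.integers(len(chroms)))])
        n_loci = len(catalog.loci_of(chrom, 1))
        length = min(
            len(assembly.sequence(chrom, 1)), len(assembly.sequence(chrom, 2))
        )
        sep = min_separation
        if sep is None:
            sep = max(1, 8 * length // (n_loci + 1)) if n_loci else 8_000
        sep = min(sep, max(1, length // 4))
        breakpoint = None
        for _try in range(60):
            junctions = sorted(
                set(assembly.junctions(chrom, 1)) | set(assembly.junctions(chrom, 2))
            )
            junctions = [j for j in junctions if sep <= j <= length - sep]
            if junctions and rng.random() < junction_prob:
                p = int(junctions[int(rng.integers(len(junctions)))])
            else:
                p = int(rng.integers(sep, length - sep))
            if not _is_intergenic(catalog, chrom, p):
                continue
            if any(abs(p - q) < sep for q in placed[chrom]):
                logger.info("breakpoint %d too close to an earlier switch; resampled", p)
                continue
            breakpoint = p
            break
        if breakpoint is None:
            logger.warning("could not place switch on chromosome %d; skipped", chrom)
            continue
        assembly, catalog, dropped = exchange_segments(
            assembly, catalog, chrom, breakpoint, breakpoint
        )
        assert dropped == 0, "intergenic breakpoint must not drop loci"
        placed[chrom].append(breakpoint)
        truth.append(
            TruthSwitch(
                genome=assembly.genome_name,
                chrom_index=chrom,
                breakpoint=breakpoint,
            )
        )
    truth.sort(key=lambda t: (t.chrom_index, t.breakpoint))
    return assembly, catalog, truth


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTrio:
    """A full synthetic study: ancestors, clean hybrids, switched hybrids."""

    model: AncestorModel
    design: HybridDesign
    ancestors: AncestorSet
    pristine_assemblies: dict[str, DiploidAssembly]
    pristine_catalogs: dict[str, LocusCatalog]
    labels: dict[tuple[str, int, int], str]
    assemblies: dict[str, DiploidAssembly]
    catalogs: dict[str, LocusCatalog]
    truth_switches: list[TruthSwitch]


def simulate_trio(
    model: AncestorModel | None = None,
    design: HybridDesign | None = None,
    switches_per_genome: int = 5,
    haplotype_noise_scale: float = 0.2,
) -> SyntheticTrio:
    """Simulate ancestors, compose hybrids, and inject switches in one pass."""
    if model is None:
        model = AncestorModel()
    if design is None:
        design = HybridDesign()
    rng = model.rng()
    ancestors = simulate_ancestors(model, rng=rng, species=design.species)
    assemblies, catalogs, labels = compose_hybrids(
        ancestors, design, rng=rng, haplotype_noise_scale=haplotype_noise_scale
    )
    switched_asm: dict[str, DiploidAssembly] = {}
    switched_cat: dict[str, LocusCatalog] = {}
    truth: list[TruthSwitch] = []
    for genome in design.genomes:
        asm, cat, t = inject_switches(
            assemblies[genome], catalogs[genome], switches_per_genome, rng
        )
        switched_asm[genome] = asm
        switched_cat[genome] = cat
        truth.extend(t)
    return SyntheticTrio(
        model=model,
        design=design,
        ancestors=ancestors,
        pristine_assemblies=assemblies,
        pristine_catalogs=catalogs,
        labels=labels,
        assemblies=switched_asm,
        catalogs=switched_cat,
        truth_switches=truth,
    )
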