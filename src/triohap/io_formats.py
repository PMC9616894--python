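"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  Conversion to the 1-based
inclusive conventions of GFF3 and AGP happens only inside the readers and
writers in this module.  BED output is 0-based half-open, as BED requires.

Sequence identifiers of placed pseudomolecules encode chromosome and
haplotype through a configurable regular expression; the default is
``(?P<chrom>chr\\d+)_hap(?P<hap>[12])``.  Any record whose id does not match
is treated as unplaced.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SeqRecord",
    "AgpComponent",
    "DiploidAssembly",
    "GeneLocus",
    "LocusCatalog",
    "AlignmentRecord",
    "VariantRecord",
    "VariantSet",
    "DEFAULT_ID_REGEX",
    "format_seq_id",
    "parse_seq_id",
    "read_fasta",
    "write_fasta",
    "assembly_from_records",
    "read_gff3",
    "write_gff3",
    "read_paf",
    "write_paf",
    "read_agp",
    "write_agp",
    "read_mummer_tables",
    "write_switch_bed",
    "write_outputs",
]

VALID_BASES = frozenset("ACGTN")

DEFAULT_ID_REGEX = r"(?P<chrom>chr\d+)_hap(?P<hap>[12])"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def format_seq_id(chrom_index: int, haplotype: int) -> str:
    """Canonical pseudomolecule id for the default id regex."""
    return f"chr{chrom_index:02d}_hap{haplotype}"


def parse_seq_id(seq_id: str, id_regex: str = DEFAULT_ID_REGEX):
    """Return ``(chrom_index, haplotype)`` or ``None`` for unplaced ids."""
    m = re.search(id_regex, seq_id)
    if m is None:
        return None
    chrom = int(re.sub(r"\D", "", m.group("chrom")))
    return chrom, int(m.group("hap"))


@dataclass
class SeqRecord:
    """A named nucleotide sequence restricted to the A,C,G,T,N alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.sequence) == 0:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains bases outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AgpComponent:
    """One component row of an AGP file, in internal 0-based coordinates.

    ``object_start``/``object_end`` are the half-open span on the assembled
    object (pseudomolecule); ``component_beg``/``component_end`` the half-open
    span on the component sequence itself (sub-contig ranges occur when a
    correction or a scaffolding error splits a contig).
    """

    object_id: str
    object_start: int
    object_end: int
    component_id: str
    orientation: str = "+"
    is_gap: bool = False
    component_beg: int = 0
    component_end: int | None = None

    def __post_init__(self) -> None:
        if self.object_start >= self.object_end:
            raise FormatError(
                f"AGP component {self.component_id!r}: empty or inverted span "
                f"[{self.object_start}, {self.object_end})"
            )
        if self.orientation not in "+-":
            raise FormatError(f"bad orientation {self.orientation!r}")
        if self.component_end is None:
            self.component_end = self.component_beg + (self.object_end - self.object_start)

    @property
    def length(self) -> int:
        return self.object_end - self.object_start


@dataclass
class GeneLocus:
    """Strand-aware gene interval; the unit of similarity voting."""

    gene_id: str
    chrom_index: int
    haplotype: int
    start: int
    end: int
    strand: str = "+"
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.haplotype not in (1, 2):
            raise FormatError(f"gene {self.gene_id!r}: bad haplotype {self.haplotype}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def unit(self) -> tuple[int, int]:
        return self.chrom_index, self.haplotype


class LocusCatalog:
    """Collection of gene loci of one genome, ranked per (chromosome, haplotype).

    Ranks are 1-based consecutive ordinals assigned by start position, ties
    broken by lexicographic gene id.
    """

    def __init__(self, genome_name: str, loci: Iterable[GeneLocus] = ()):  # noqa: D401
        self.genome_name = genome_name
        self.loci: list[GeneLocus] = list(loci)
        self._check_unique_ids()
        self.assign_ranks()

    def _check_unique_ids(self) -> None:
        seen: set[str] = set()
        for locus in self.loci:
            if locus.gene_id in seen:
                raise FormatError(f"duplicate gene id {locus.gene_id!r}")
            seen.add(locus.gene_id)

    def assign_ranks(self) -> None:
        self.loci.sort(key=lambda g: (g.chrom_index, g.haplotype, g.start, g.gene_id))
        by_unit: dict[tuple[int, int], int] = {}
        for locus in self.loci:
            by_unit[locus.unit] = by_unit.get(locus.unit, 0) + 1
            locus.rank = by_unit[locus.unit]
        self._by_id = {g.gene_id: g for g in self.loci}
        self._by_unit: dict[tuple[int, int], list[GeneLocus]] = {}
        for locus in self.loci:
            self._by_unit.setdefault(locus.unit, []).append(locus)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def by_id(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def loci_of(self, chrom_index: int, haplotype: int) -> list[GeneLocus]:
        return self._by_unit.get((chrom_index, haplotype), [])

    @property
    def units(self) -> list[tuple[int, int]]:
        return sorted(self._by_unit)


@dataclass
class DiploidAssembly:
    """Per-genome container of pseudomolecules keyed by (chromosome, haplotype)."""

    genome_name: str
    chromosomes: dict[tuple[int, int], SeqRecord] = field(default_factory=dict)
    unplaced: list[SeqRecord] = field(default_factory=list)
    components: list[AgpComponent] = field(default_factory=list)

    def validate(self) -> None:
        chroms = {c for c, _h in self.chromosomes}
        for c in chroms:
            if (c, 1) not in self.chromosomes or (c, 2) not in self.chromosomes:
                raise FormatError(
                    f"{self.genome_name}: chromosome {c} lacks one of its two haplotypes"
                )
        self.validate_components()

    def validate_components(self) -> None:
        """Components must tile each pseudomolecule without gaps or overlaps."""
        if not self.components:
            return
        by_obj: dict[str, list[AgpComponent]] = {}
        for comp in self.components:
            by_obj.setdefault(comp.object_id, []).append(comp)
        for (c, h), rec in self.chromosomes.items():
            comps = sorted(by_obj.get(rec.id, []), key=lambda x: x.object_start)
            if not comps:
                continue
            pos = 0
            for comp in comps:
                if comp.object_start != pos:
                    raise FormatError(
                        f"{rec.id}: component {comp.component_id!r} starts at "
                        f"{comp.object_start}, expected {pos}"
                    )
                pos = comp.object_end
            if pos != len(rec):
                raise FormatError(
                    f"{rec.id}: components end at {pos}, sequence length {len(rec)}"
                )

    @property
    def n_chromosomes(self) -> int:
        return len({c for c, _h in self.chromosomes})

    def sequence(self, chrom_index: int, haplotype: int) -> str:
        return self.chromosomes[(chrom_index, haplotype)].sequence

    def components_of(self, chrom_index: int, haplotype: int) -> list[AgpComponent]:
        obj = self.chromosomes[(chrom_index, haplotype)].id
        return sorted(
            (c for c in self.components if c.object_id == obj),
            key=lambda c: c.object_start,
        )

    def junctions(self, chrom_index: int, haplotype: int) -> list[int]:
        """Interior component junction positions of one pseudomolecule."""
        comps = self.components_of(chrom_index, haplotype)
        return [c.object_end for c in comps[:-1]]

    def all_records(self) -> list[SeqRecord]:
        placed = [self.chromosomes[k] for k in sorted(self.chromosomes)]
        return placed + list(self.unplaced)


@dataclass
class AlignmentRecord:
    """One PAF alignment row (mandatory columns only)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.block_len):
            raise FormatError(
                f"alignment {self.query_id}->{self.target_id}: "
                f"matches {self.matches} outside [0, {self.block_len}]"
            )
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_len

    @property
    def target_coverage(self) -> float:
        return (self.target_end - self.target_start) / self.target_len


@dataclass
class VariantRecord:
    """A SNP, short indel, or structural variant between two haplotypes.

    ``ref_start``/``ref_end`` is the affected half-open span on the reference
    side.  Pure insertions relative to the reference affect a single junction
    base (span 1).  The kind is classified from the larger of the reference
    span and ``alt_len``: 1 bp substitutions are SNPs, events of at most
    50 bp are INDELs, and anything larger is an SV.
    """

    kind: str
    ref_chrom: tuple[int, int]
    ref_start: int
    ref_end: int
    alt_len: int = 0
    alt_seq: str | None = None
    other_start: int | None = None

    SNP = "SNP"
    INDEL = "INDEL"
    SV = "SV"

    def __post_init__(self) -> None:
        if self.kind not in (self.SNP, self.INDEL, self.SV):
            raise FormatError(f"unknown variant kind {self.kind!r}")
        span = self.ref_end - self.ref_start
        if self.kind == self.SNP and span != 1:
            raise FormatError(f"SNP with span {span}")
        size = max(span, self.alt_len)
        if self.kind == self.INDEL and size > 50:
            raise FormatError(f"INDEL with affected size {size} > 50")
        if self.kind == self.SV and size <= 50:
            raise FormatError(f"SV with affected size {size} <= 50")

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


def classify_variant_kind(ref_span: int, alt_len: int) -> str:
    size = max(ref_span, alt_len)
    if size == 1 and ref_span == 1 and alt_len == 1:
        return VariantRecord.SNP
    return VariantRecord.INDEL if size <= 50 else VariantRecord.SV


class VariantSet:
    """Bag of variant records between one ordered haplotype pair."""

    def __init__(self, records: Iterable[VariantRecord] = ()):  # noqa: D401
        self.records: list[VariantRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def add(self, record: VariantRecord) -> None:
        self.records.append(record)

    def extend(self, records: Iterable[VariantRecord]) -> None:
        self.records.extend(records)

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r.kind == kind)

    def by_kind(self) -> dict[str, int]:
        return {k: self.count(k) for k in (VariantRecord.SNP, VariantRecord.INDEL, VariantRecord.SV)}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, keep_softmask: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`, in file order.

    Sequences are uppercased unless ``keep_softmask`` is set.  Duplicate ids
    and empty sequences are errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not keep_softmask:
            seq = seq.upper()
        records.append(SeqRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[SeqRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def assembly_from_records(
    genome_name: str,
    records: Sequence[SeqRecord],
    id_regex: str = DEFAULT_ID_REGEX,
    components: Iterable[AgpComponent] = (),
) -> DiploidAssembly:
    """Group FASTA records into a diploid assembly by the id regex."""
    asm = DiploidAssembly(genome_name=genome_name, components=list(components))
    for rec in records:
        key = parse_seq_id(rec.id, id_regex)
        if key is None:
            asm.unplaced.append(rec)
        else:
            if key in asm.chromosomes:
                raise FormatError(
                    f"{genome_name}: two records map to chromosome/haplotype {key}"
                )
            asm.chromosomes[key] = rec
    asm.validate()
    return asm


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path,
    genome_name: str | None = None,
    id_regex: str = DEFAULT_ID_REGEX,
    feature_type: str = "gene",
) -> LocusCatalog:
    """Read gene features from a GFF3 file into a ranked locus catalog.

    GFF3 coordinates are 1-based inclusive; they are converted to internal
    0-based half-open here.  Features on seqids that do not match the id
    regex are an error (genes must live on placed pseudomolecules).
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            key = parse_seq_id(seqid, id_regex)
            if key is None:
                raise FormatError(
                    f"{path}:{lineno}: seqid {seqid!r} does not match id regex {id_regex!r}"
                )
            gene_id = None
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    if k.strip() == "ID":
                        gene_id = v.strip()
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    chrom_index=key[0],
                    haplotype=key[1],
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else "+",
                )
            )
    name = genome_name if genome_name is not None else Path(str(path)).stem
    return LocusCatalog(name, loci)


def write_gff3(catalog: LocusCatalog, path, source: str = "triohap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in sorted(
            catalog.loci, key=lambda g: (g.chrom_index, g.haplotype, g.start, g.gene_id)
        ):
            seqid = format_seq_id(locus.chrom_index, locus.haplotype)
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        "gene",
                        str(locus.start + 1),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path) -> list[AlignmentRecord]:
    """Parse the 12 mandatory PAF columns, in file order."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: PAF line has {len(f)} < 12 columns")
            records.append(
                AlignmentRecord(
                    query_id=f[0],
                    query_len=int(f[1]),
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    target_id=f[5],
                    target_len=int(f[6]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    matches=int(f[9]),
                    block_len=int(f[10]),
                    mapq=int(f[11]),
                )
            )
    return records


def write_paf(records: Sequence[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.query_len, r.query_start, r.query_end,
                        r.strand,
                        r.target_id, r.target_len, r.target_start, r.target_end,
                        r.matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

def write_agp(components: Sequence[AgpComponent], path) -> None:
    """Write AGP v2.1; object and component coordinates become 1-based inclusive."""
    by_obj: dict[str, list[AgpComponent]] = {}
    for comp in components:
        by_obj.setdefault(comp.object_id, []).append(comp)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for obj in sorted(by_obj):
            rows = sorted(by_obj[obj], key=lambda c: c.object_start)
            for part, comp in enumerate(rows, start=1):
                if comp.is_gap:
                    fh.write(
                        "\t".join(
                            [
                                obj,
                                str(comp.object_start + 1),
                                str(comp.object_end),
                                str(part),
                                "N",
                                str(comp.length),
                                "scaffold",
                                "yes",
                                "align_genus",
                            ]
                        )
                        + "\n"
                    )
                else:
                    fh.write(
                        "\t".join(
                            [
                                obj,
                                str(comp.object_start + 1),
                                str(comp.object_end),
                                str(part),
                                "W",
                                comp.component_id,
                                str(comp.component_beg + 1),
                                str(comp.component_end),
                                comp.orientation,
                            ]
                        )
                        + "\n"
                    )


def read_agp(path) -> list[AgpComponent]:
    comps: list[AgpComponent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: AGP row has {len(f)} < 9 columns")
            obj, beg1, end1, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            if ctype in ("N", "U"):
                comps.append(
                    AgpComponent(
                        object_id=obj,
                        object_start=beg1 - 1,
                        object_end=end1,
                        component_id=f"gap_{lineno}",
                        is_gap=True,
                    )
                )
            else:
                comps.append(
                    AgpComponent(
                        object_id=obj,
                        object_start=beg1 - 1,
                        object_end=end1,
                        component_id=f[5],
                        component_beg=int(f[6]) - 1,
                        component_end=int(f[7]),
                        orientation=f[8] if f[8] in "+-" else "+",
                    )
                )
    return comps


# ---------------------------------------------------------------------------
# MUMmer show-snps / show-diff tables
# ---------------------------------------------------------------------------

def _is_header(fields: list[str]) -> bool:
    if not fields:
        return True
    try:
        int(fields[0])
        return False
    except ValueError:
        return True


def read_mummer_tables(snps_path=None, diff_path=None, ref_chrom=(1, 1)) -> VariantSet:
    """Import MUMmer ``show-snps`` (-Clr -x dialect) and ``show-diff`` tables.

    show-snps rows with a ``.`` allele denote single-base indel columns;
    consecutive rows of the same indel run are merged into one INDEL or SV
    record by run length.  show-diff features (GAP, BRK, JMP, DUP, SEQ, INV)
    become SV spans on the reference side; non-positive spans (overlapping
    alignments) are skipped.
    """
    variants = VariantSet()
    if snps_path is not None:
        rows = []
        with open(snps_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if _is_header(fields):
                    continue
                if len(fields) < 4:
                    raise FormatError(f"{snps_path}:{lineno}: unparseable show-snps row")
                try:
                    p1 = int(fields[0])
                    ref_al, qry_al = fields[1], fields[2]
                    p2 = int(fields[3])
                except ValueError as exc:
                    raise FormatError(
                        f"{snps_path}:{lineno}: unparseable show-snps row"
                    ) from exc
                rows.append((p1, ref_al, qry_al, p2))
        variants.extend(_merge_snps_rows(rows, ref_chrom))
    if diff_path is not None:
        with open(diff_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if _is_header(fields) and (len(fields) < 3 or not fields[2].lstrip("-").isdigit()):
                    continue
                if len(fields) < 4:
                    raise FormatError(f"{diff_path}:{lineno}: unparseable show-diff row")
                try:
                    s1, e1 = int(fields[2]), int(fields[3])
                except ValueError as exc:
                    raise FormatError(
                        f"{diff_path}:{lineno}: unparseable show-diff row"
                    ) from exc
                span = e1 - s1 + 1
                if span <= 0:
                    continue
                kind = classify_variant_kind(span, 0)
                if kind == VariantRecord.SNP:
                    kind = VariantRecord.INDEL
                variants.add(
                    VariantRecord(
                        kind=kind,
                        ref_chrom=ref_chrom,
                        ref_start=s1 - 1,
                        ref_end=e1,
                    )
                )
    return variants


def _merge_snps_rows(rows, ref_chrom) -> list[VariantRecord]:
    """Merge show-snps rows into SNP records and run-length merged indels."""
    out: list[VariantRecord] = []
    covered: set[int] = set()
    i = 0
    rows = list(rows)
    while i < len(rows):
        p1, ref_al, qry_al, p2 = rows[i]
        if ref_al != "." and qry_al != ".":
            out.append(
                VariantRecord(
                    kind=VariantRecord.SNP,
                    ref_chrom=ref_chrom,
                    ref_start=p1 - 1,
                    ref_end=p1,
                    alt_len=1,
                    alt_seq=qry_al,
                    other_start=p2 - 1,
                )
            )
            i += 1
            continue
        if ref_al == ".":
            # insertion run: reference position constant, query advances
            j = i
            alt = []
            while j < len(rows) and rows[j][1] == "." and rows[j][0] == p1:
                alt.append(rows[j][2])
                j += 1
            if p1 - 1 in covered:
                warnings.warn(
                    f"overlapping merged indel at reference position {p1}; merged"
                )
            covered.add(p1 - 1)
            alt_seq = "".join(alt)
            out.append(
                VariantRecord(
                    kind=classify_variant_kind(1, len(alt_seq)) if len(alt_seq) > 1
                    else VariantRecord.INDEL,
                    ref_chrom=ref_chrom,
                    ref_start=p1 - 1,
                    ref_end=p1,
                    alt_len=len(alt_seq),
                    alt_seq=alt_seq,
                    other_start=p2 - 1,
                )
            )
            i = j
        else:
            # deletion run: query position constant, reference advances
            j = i
            start = p1
            prev = p1 - 1
            while (
                j < len(rows)
                and rows[j][2] == "."
                and rows[j][0] == prev + 1
            ):
                prev = rows[j][0]
                j += 1
            span = prev - start + 1
            if any(p in covered for p in range(start - 1, prev)):
                warnings.warn(
                    f"overlapping merged indel at reference span {start}-{prev}; merged"
                )
            covered.update(range(start - 1, prev))
            out.append(
                VariantRecord(
                    kind=classify_variant_kind(span, 0),
                    ref_chrom=ref_chrom,
                    ref_start=start - 1,
                    ref_end=prev,
                    alt_len=0,
                    alt_seq="",
                    other_start=p2 - 1,
                )
            )
            i = j
    return out


# ---------------------------------------------------------------------------
# BED and result bundles
# ---------------------------------------------------------------------------

def write_switch_bed(switches, path) -> None:
    """Write switch breakpoints as BED (0-based half-open) with a header line.

    Accepts objects exposing ``chrom_index`` plus either a point
    ``breakpoint`` (truth) or a ``breakpoint_interval`` (detected events).
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for sw in switches:
            if hasattr(sw, "breakpoint_interval"):
                start, end = sw.breakpoint_interval
                name = f"{sw.genome}:{sw.upstream_species}>{sw.downstream_species}"
            else:
                start, end = sw.breakpoint, sw.breakpoint + 1
                name = f"{sw.genome}:truth"
            fh.write(
                f"{format_seq_id(sw.chrom_index, 1)}\t{start}\t{end}\t{name}\n"
            )


def write_outputs(results: Mapping, out_dir, force: bool = False) -> list[str]:
    """Write the result bundle of a pipeline run; byte-deterministic.

    ``results`` maps well-known keys to objects: ``assemblies`` (list of
    DiploidAssembly), ``catalogs`` (list of LocusCatalog), ``truth_switches``,
    ``predicted_switches``, ``summary`` (JSON-serializable mapping), and
    ``tables`` (mapping name -> pandas DataFrame).
    """
    out = Path(out_dir)
    # the run log lives in the output directory and does not count as content
    if (
        out.exists()
        and any(p.name != "triohap.log" for p in out.iterdir())
        and not force
    ):
        raise FileExistsError(f"output directory {out} exists; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _note(p: Path) -> None:
        written.append(str(p.relative_to(out)))

    for asm in results.get("assemblies", []):
        p = out / f"{asm.genome_name}.fasta"
        write_fasta(asm.all_records(), p)
        _note(p)
        if asm.components:
            p = out / f"{asm.genome_name}.agp"
            write_agp(asm.components, p)
            _note(p)
    for cat in results.get("catalogs", []):
        p = out / f"{cat.genome_name}.gff3"
        write_gff3(cat, p)
        _note(p)
    for key in ("truth_switches", "predicted_switches"):
        if key in results:
            by_genome: dict[str, list] = {}
            for sw in results[key]:
                by_genome.setdefault(sw.genome, []).append(sw)
            for genome in sorted(by_genome):
                p = out / f"{genome}.{key}.bed"
                write_switch_bed(by_genome[genome], p)
                _note(p)
            if not by_genome:
                p = out / f"{key}.bed"
                write_switch_bed([], p)
                _note(p)
    for name, frame in sorted(results.get("tables", {}).items()):
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        _note(p)
    if "summary" in results:
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(results["summary"], fh, indent=2, sort_keys=True)
            fh.write("\n")
        _note(p)
    return written
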