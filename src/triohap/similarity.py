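"""Gene-locus similarity scoring and best-hit tables.

Loci are compared as genomic substrings (introns included), minus-strand
loci reverse-complemented.  Scoring is a deterministic two-stage procedure:
a shared-minimizer prefilter proposes candidate pairs, and edlib computes a
global ("NW") or glocal ("HW", full query inside target) alignment from
which identity and coverages are derived.  N bases never count as
mismatches, and loci that are mostly N are excluded from voting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import pandas as pd

from ._kmers import minimizer_set
from .io_formats import DiploidAssembly, GeneLocus, LocusCatalog

__all__ = [
    "LocusMatch",
    "BestHitTable",
    "extract_locus_sequences",
    "score_pair",
    "best_hits",
    "reverse_complement",
    "n_fraction",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# N aligns with anything at no penalty, so masked bases do not enter the
# mismatch count.
_N_EQUALITIES = [("N", b) for b in "ACGTN"]

MAX_N_FRACTION = 0.5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def extract_locus_sequences(
    assembly: DiploidAssembly, catalog: LocusCatalog
) -> dict[str, str]:
    """Extract the genomic sequence of every locus, oriented 5'->3'.

    Minus-strand loci are reverse-complemented.  A locus outside its
    pseudomolecule is an error naming the gene.
    """
    out: dict[str, str] = {}
    for locus in catalog:
        try:
            chrom_seq = assembly.sequence(locus.chrom_index, locus.haplotype)
        except KeyError as exc:
            raise ValueError(
                f"gene {locus.gene_id!r}: no pseudomolecule "
                f"({locus.chrom_index}, {locus.haplotype}) in {assembly.genome_name}"
            ) from exc
        if locus.end > len(chrom_seq):
            raise ValueError(
                f"gene {locus.gene_id!r}: span [{locus.start}, {locus.end}) exceeds "
                f"pseudomolecule length {len(chrom_seq)}"
            )
        seq = chrom_seq[locus.start : locus.end]
        out[locus.gene_id] = reverse_complement(seq) if locus.strand == "-" else seq
    return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, block_len) from an extended cigar string (=, X, I, D)."""
    matches = block = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            block += num
            if ch == "=":
                matches += num
            num = 0
    return matches, block


def score_pair(seq_a: str, seq_b: str, mode: str = "glocal") -> tuple[float, float, float]:
    """Align two locus sequences; return (identity, coverage_a, coverage_b).

    Identity is matches / alignment block length.  In glocal mode the
    shorter sequence is aligned end-to-end inside the longer one, so the
    shorter side's coverage is 1.0 and the longer side's coverage is the
    aligned target span over its length.  The identity is symmetric in the
    argument order.
    """
    if not seq_a or not seq_b:
        raise ValueError("score_pair requires non-empty sequences")
    if mode not in ("global", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    flipped = len(seq_b) < len(seq_a)
    query, target = (seq_b, seq_a) if flipped else (seq_a, seq_b)
    edlib_mode = "NW" if mode == "global" else "HW"
    res = edlib.align(
        query, target, mode=edlib_mode, task="path", additionalEqualities=_N_EQUALITIES
    )
    matches, block = _cigar_stats(res["cigar"])
    identity = matches / block if block else 0.0
    cov_query = 1.0
    if mode == "global":
        cov_target = 1.0
    else:
        start, end = res["locations"][0]
        cov_target = (end + 1 - start) / len(target)
    cov_a, cov_b = (cov_target, cov_query) if flipped else (cov_query, cov_target)
    return identity, cov_a, cov_b


@dataclass
class LocusMatch:
    """Best-scoring alignment between a query locus and one foreign locus."""

    query: GeneLocus
    target: GeneLocus
    target_genome: str
    identity: float
    coverage_query: float
    coverage_target: float

    @property
    def ranking_key(self):
        # maximized; deterministic total order (paper's "highest coverage
        # and identity" is not one)
        return (
            self.identity * self.coverage_query,
            self.identity,
            # lexicographically smaller target id wins ties
            tuple(-ord(c) for c in self.target.gene_id),
        )

    @property
    def target_unit(self) -> tuple[str, int]:
        return self.target_genome, self.target.haplotype


class BestHitTable:
    """At most one best match per (query locus, foreign genome+haplotype)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, tuple[str, int]], LocusMatch] = {}

    def offer(self, match: LocusMatch) -> None:
        key = (match.query.gene_id, match.target_unit)
        cur = self._entries.get(key)
        if cur is None or match.ranking_key > cur.ranking_key:
            self._entries[key] = match

    def get(self, query_gene_id: str, unit: tuple[str, int]) -> LocusMatch | None:
        return self._entries.get((query_gene_id, unit))

    def matches(self) -> list[LocusMatch]:
        return [self._entries[k] for k in sorted(self._entries)]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self.matches())

    def update(self, other: "BestHitTable") -> None:
        for match in other:
            self.offer(match)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_gene": m.query.gene_id,
                "query_unit": f"chr{m.query.chrom_index}_hap{m.query.haplotype}",
                "target_genome": m.target_genome,
                "target_gene": m.target.gene_id,
                "target_unit": f"chr{m.target.chrom_index}_hap{m.target.haplotype}",
                "identity": m.identity,
                "coverage_query": m.coverage_query,
                "coverage_target": m.coverage_target,
            }
            for m in self.matches()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "query_gene", "query_unit", "target_genome", "target_gene",
                "target_unit", "identity", "coverage_query", "coverage_target",
            ],
        )


def best_hits(
    query_catalog: LocusCatalog,
    query_seqs: Mapping[str, str],
    foreign: Mapping[str, tuple[LocusCatalog, Mapping[str, str]]],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    k: int = 15,
    min_shared: int = 10,
    prefilter: bool = True,
    mode: str = "glocal",
) -> BestHitTable:
    """Best foreign hit of every query locus, per foreign (genome, haplotype).

    Candidate pairs come from a shared-minimizer prefilter (``k``-mers,
    at least ``min_shared`` shared minimizers); candidates are then scored
    with :func:`score_pair` and ranked by identity x query coverage, ties
    broken by identity then target gene id.  Entries below the identity or
    coverage floors are dropped, as are loci that are more than half N.
    """
    table = BestHitTable()
    if not foreign:
        return table

    foreign_index: dict[str, dict[str, GeneLocus]] = {}
    foreign_minimizers: dict[str, dict[str, frozenset[int]]] = {}
    inverted: dict[str, dict[int, list[str]]] = {}
    for genome, (catalog, seqs) in foreign.items():
        foreign_index[genome] = {g.gene_id: g for g in catalog}
        mins: dict[str, frozenset[int]] = {}
        inv: dict[int, list[str]] = {}
        for locus in catalog:
            seq = seqs[locus.gene_id]
            if n_fraction(seq) > MAX_N_FRACTION:
                continue
            ms = minimizer_set(seq, k=k)
            mins[locus.gene_id] = ms
            for v in ms:
                inv.setdefault(v, []).append(locus.gene_id)
        foreign_minimizers[genome] = mins
        inverted[genome] = inv

    for query in query_catalog:
        qseq = query_seqs[query.gene_id]
        if n_fraction(qseq) > MAX_N_FRACTION:
            continue
        qmin = minimizer_set(qseq, k=k) if prefilter else None
        for genome, (catalog, seqs) in foreign.items():
            if prefilter:
                counts: Counter[str] = Counter()
                inv = inverted[genome]
                for v in qmin:
                    for gid in inv.get(v, ()):
                        counts[gid] += 1
                candidates = sorted(g for g, c in counts.items() if c >= min_shared)
            else:
                candidates = sorted(foreign_minimizers[genome])
            for gid in candidates:
                target = foreign_index[genome][gid]
                identity, cov_q, cov_t = score_pair(qseq, seqs[gid], mode=mode)
                if identity < min_identity or cov_q < min_coverage:
                    continue
                table.offer(
                    LocusMatch(
                        query=query,
                        target=target,
                        target_genome=genome,
                        identity=identity,
                        coverage_query=cov_q,
                        coverage_target=cov_t,
                    )
                )
    return table
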