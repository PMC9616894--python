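"""Inter-haplotype variant detection and the unaffected-length statistic.

Two haplotype sequences are compared with a desk-scale anchor-chain
aligner: unique shared 21-mers anchor the alignment, anchors are chained by
a longest-increasing-subsequence pass on both coordinates, inter-anchor
gaps are closed by global alignment when small, and larger gaps become
structural-variant spans.  Variants are classified as SNPs, short indels
(<= 50 bp) or SVs (> 50 bp).

The similarity between two haplotypes is the percentage of the reference
haploid chromosome-set length not affected by any variant: affected spans
(SNP positions, indel spans, SV spans) are unioned on reference
coordinates, overlaps counted once.  Unaligned reference sequence counts as
affected.  Shared-species versus non-shared-species similarity groups are
compared with an unpaired two-sample rank-sum test (exact by enumeration
for small groups, normal approximation with tie and continuity corrections
otherwise).
"""

from __future__ import annotations

import bisect
import itertools
import logging
import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from ._kmers import shared_unique_anchors
from .io_formats import VariantRecord, VariantSet, classify_variant_kind

__all__ = [
    "HaplotypePairComparison",
    "GroupComparison",
    "align_haplotypes",
    "apply_variants",
    "affected_union",
    "unaffected_fraction",
    "rank_sum_test",
    "grouped_similarity",
    "compare_haplotype_pair",
]

logger = logging.getLogger(__name__)

MAX_DESK_LENGTH = 10_000_000
MAX_GAP_CLOSE = 20_000


def _merge_anchor_runs(pos_a: np.ndarray, pos_b: np.ndarray, k: int):
    """Collapse diagonal runs of anchors into (a, b, covered_length) triples."""
    if pos_a.size == 0:
        return []
    da = np.diff(pos_a)
    db = np.diff(pos_b)
    breaks = np.flatnonzero((da != 1) | (db != 1))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos_a.size - 1]))
    return [
        (int(pos_a[s]), int(pos_b[s]), int(pos_a[e] - pos_a[s]) + k)
        for s, e in zip(starts, ends)
    ]


def _lis_chain(runs):
    """Longest chain of runs strictly increasing in both coordinates.

    Runs are pre-sorted by the a-coordinate; patience sorting on the
    b-coordinate yields the chain in O(n log n).
    """
    if not runs:
        return []
    tails_b: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(runs)
    for i, (_a, b, _l) in enumerate(runs):
        j = bisect.bisect_left(tails_b, b)
        if j > 0:
            parent[i] = tails_idx[j - 1]
        if j == len(tails_b):
            tails_b.append(b)
            tails_idx.append(i)
        else:
            tails_b[j] = b
            tails_idx[j] = i
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(runs[i])
        i = parent[i]
    return chain[::-1]


def _gap_variants(ref_gap: str, other_gap: str, ref_off: int, other_off: int,
                  ref_chrom, ref_total: int) -> list[VariantRecord]:
    """Close one inter-anchor gap with a global alignment; emit variants."""
    res = edlib.align(other_gap, ref_gap, mode="NW", task="path")
    out: list[VariantRecord] = []
    rp, op = 0, 0
    num = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num = num * 10 + int(ch)
            continue
        if ch == "=":
            rp += num
            op += num
        elif ch == "X":
            for t in range(num):
                out.append(
                    VariantRecord(
                        kind=VariantRecord.SNP,
                        ref_chrom=ref_chrom,
                        ref_start=ref_off + rp + t,
                        ref_end=ref_off + rp + t + 1,
                        alt_len=1,
                        alt_seq=other_gap[op + t],
                        other_start=other_off + op + t,
                    )
                )
            rp += num
            op += num
        elif ch == "D":
            # consumes reference only: deletion from the reference
            out.append(
                VariantRecord(
                    kind=classify_variant_kind(num, 0),
                    ref_chrom=ref_chrom,
                    ref_start=ref_off + rp,
                    ref_end=ref_off + rp + num,
                    alt_len=0,
                    alt_seq="",
                    other_start=other_off + op,
                )
            )
            rp += num
        elif ch == "I":
            # consumes the other sequence only: insertion; affects one
            # junction base on the reference
            junction = min(ref_off + rp, ref_total - 1)
            out.append(
                VariantRecord(
                    kind=VariantRecord.INDEL if num <= 50 else VariantRecord.SV,
                    ref_chrom=ref_chrom,
                    ref_start=junction,
                    ref_end=junction + 1,
                    alt_len=num,
                    alt_seq=other_gap[op : op + num],
                    other_start=other_off + op,
                )
            )
            op += num
        num = 0
    return out


def align_haplotypes(
    ref_seq: str,
    other_seq: str,
    ref_chrom=(1, 1),
    k: int = 21,
    max_gap_close: int = MAX_GAP_CLOSE,
) -> VariantSet:
    """Pairwise variant detection between two haplotype sequences.

    Desk-scale only (inputs <= 10 Mbp; larger comparisons should come in
    through the MUMmer-table import path).  Pure insertions affect a single
    reference junction base; every unaligned or unalignable reference span
    is emitted as an affected span.
    """
    if len(ref_seq) > MAX_DESK_LENGTH or len(other_seq) > MAX_DESK_LENGTH:
        raise ValueError(
            "align_haplotypes is desk-scale (<= 10 Mbp); use the MUMmer import"
        )
    if ref_seq == other_seq:
        return VariantSet()
    pos_a, pos_b = shared_unique_anchors(ref_seq, other_seq, k=k)
    runs = _merge_anchor_runs(pos_a, pos_b, k)
    chain = _lis_chain(runs)
    variants = VariantSet()
    if not chain:
        logger.warning("no alignment anchors found; whole sequence emitted as SV")
        span = len(ref_seq)
        variants.add(
            VariantRecord(
                kind=classify_variant_kind(span, len(other_seq)),
                ref_chrom=ref_chrom,
                ref_start=0,
                ref_end=span,
                alt_len=len(other_seq),
            )
        )
        return variants

    # trim overlapping neighbours (anchors may overlap within k-1 bases)
    cleaned = []
    prev_a_end, prev_b_end = -1, -1
    for a, b, length in chain:
        ov = max(prev_a_end - a, prev_b_end - b, 0)
        a, b, length = a + ov, b + ov, length - ov
        if length <= 0:
            continue
        cleaned.append((a, b, length))
        prev_a_end, prev_b_end = a + length, b + length

    segments = [(0, 0, 0)] + cleaned + [(len(ref_seq), len(other_seq), 0)]
    for (pa, pb, plen), (a, b, _l) in zip(segments, segments[1:]):
        ref_gap = (pa + plen, a)
        other_gap = (pb + plen, b)
        rlen = ref_gap[1] - ref_gap[0]
        olen = other_gap[1] - other_gap[0]
        if rlen == 0 and olen == 0:
            continue
        if rlen <= max_gap_close and olen <= max_gap_close:
            # fast paths for the overwhelmingly common tiny gaps
            if rlen == 0:
                junction = min(ref_gap[0], len(ref_seq) - 1)
                variants.add(
                    VariantRecord(
                        kind=VariantRecord.INDEL if olen <= 50 else VariantRecord.SV,
                        ref_chrom=ref_chrom,
                        ref_start=junction,
                        ref_end=junction + 1,
                        alt_len=olen,
                        alt_seq=other_seq[other_gap[0] : other_gap[1]],
                        other_start=other_gap[0],
                    )
                )
            elif olen == 0:
                variants.add(
                    VariantRecord(
                        kind=classify_variant_kind(rlen, 0),
                        ref_chrom=ref_chrom,
                        ref_start=ref_gap[0],
                        ref_end=ref_gap[1],
                        alt_len=0,
                        alt_seq="",
                        other_start=other_gap[0],
                    )
                )
            elif rlen == olen and rlen <= 30:
                for t in range(rlen):
                    rb = ref_seq[ref_gap[0] + t]
                    ob = other_seq[other_gap[0] + t]
                    if rb != ob:
                        variants.add(
                            VariantRecord(
                                kind=VariantRecord.SNP,
                                ref_chrom=ref_chrom,
                                ref_start=ref_gap[0] + t,
                                ref_end=ref_gap[0] + t + 1,
                                alt_len=1,
                                alt_seq=ob,
                                other_start=other_gap[0] + t,
                            )
                        )
            else:
                variants.extend(
                    _gap_variants(
                        ref_seq[ref_gap[0] : ref_gap[1]],
                        other_seq[other_gap[0] : other_gap[1]],
                        ref_gap[0],
                        other_gap[0],
                        ref_chrom,
                        len(ref_seq),
                    )
                )
        else:
            span = max(rlen, 1)
            variants.add(
                VariantRecord(
                    kind=classify_variant_kind(span, olen),
                    ref_chrom=ref_chrom,
                    ref_start=ref_gap[0],
                    ref_end=ref_gap[0] + span,
                    alt_len=olen,
                    other_start=other_gap[0],
                )
            )
    return variants


def apply_variants(ref_seq: str, variants: VariantSet) -> str:
    """Reconstruct the other haplotype by editing the reference.

    Only valid for variant sets carrying alternate sequence content (the
    output of :func:`align_haplotypes` on SV-free comparisons).
    """
    records = sorted(variants, key=lambda v: (v.ref_start, v.alt_len == 0))
    pieces: list[str] = []
    cur = 0
    for v in records:
        if v.alt_seq is None:
            raise ValueError("variant without alternate content; cannot rebuild")
        if v.kind == VariantRecord.SNP:
            pieces.append(ref_seq[cur : v.ref_start])
            pieces.append(v.alt_seq)
            cur = v.ref_end
        elif v.alt_len == 0:  # deletion from reference
            pieces.append(ref_seq[cur : v.ref_start])
            cur = v.ref_end
        else:  # insertion before ref_start
            pieces.append(ref_seq[cur : v.ref_start])
            pieces.append(v.alt_seq)
            cur = v.ref_start
    pieces.append(ref_seq[cur:])
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Unaffected-length statistic
# ---------------------------------------------------------------------------


def affected_union(variants: VariantSet, ref_length: int) -> int:
    """Total bp of the union of affected reference spans (overlaps once)."""
    spans = []
    for v in variants:
        if v.ref_start < 0 or v.ref_end > ref_length:
            raise ValueError(
                f"variant span [{v.ref_start}, {v.ref_end}) outside reference "
                f"of length {ref_length}"
            )
        spans.append((v.ref_start, v.ref_end))
    spans.sort()
    total = 0
    cur_s, cur_e = None, None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def unaffected_fraction(per_chromosome: list[tuple[VariantSet, int]]) -> float:
    """Similarity percentage over a haploid chromosome set.

    ``per_chromosome`` pairs each reference pseudomolecule's variant set
    with its length; the statistic is 100 x (1 - affected / haploid length)
    aggregated over the whole set.
    """
    affected = sum(affected_union(vs, length) for vs, length in per_chromosome)
    haploid = sum(length for _vs, length in per_chromosome)
    if haploid == 0:
        raise ValueError("empty chromosome set")
    return 100.0 * (1.0 - affected / haploid)


@dataclass
class HaplotypePairComparison:
    """One directional whole-haplotype comparison."""

    ref_unit: tuple[str, str]
    other_unit: tuple[str, str]
    variants_by_chrom: dict[int, VariantSet]
    haploid_length: int
    affected: int
    shared_species: bool

    @property
    def similarity_pct(self) -> float:
        return 100.0 * (1.0 - self.affected / self.haploid_length)

    def variant_counts(self) -> dict[str, int]:
        out = {"SNP": 0, "INDEL": 0, "SV": 0}
        for vs in self.variants_by_chrom.values():
            for kind, n in vs.by_kind().items():
                out[kind] += n
        return out


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Unpaired two-sample rank-sum comparison of two similarity groups."""

    group1: list[float]
    group2: list[float]
    W: float
    p_value: float
    method: str

    # the grouped pipeline puts the shared-species group first
    @property
    def shared_group(self) -> list[float]:
        return self.group1

    @property
    def nonshared_group(self) -> list[float]:
        return self.group2


def _u_statistic(group1, group2) -> float:
    w = 0.0
    for x in group1:
        for y in group2:
            if x > y:
                w += 1.0
            elif x == y:
                w += 0.5
    return w


def rank_sum_test(group1, group2, exact_limit: int = 20) -> GroupComparison:
    """Rank-sum test with W = number of (x, y) pairs with x > y (ties half).

    Exact two-sided p by enumeration over all assignments of the pooled
    values when n1 + n2 <= ``exact_limit`` (ties handled by direct pair
    counting); otherwise the normal approximation with tie and continuity
    corrections.
    """
    group1, group2 = list(map(float, group1)), list(map(float, group2))
    n1, n2 = len(group1), len(group2)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    w = _u_statistic(group1, group2)
    if n1 + n2 <= exact_limit:
        pooled = group1 + group2
        idx = range(n1 + n2)
        lower = higher = total = 0
        for combo in itertools.combinations(idx, n1):
            chosen = set(combo)
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in idx if i not in chosen]
            u = _u_statistic(g1, g2)
            total += 1
            if u <= w:
                lower += 1
            if u >= w:
                higher += 1
        p = min(1.0, 2.0 * min(lower / total, higher / total))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        pooled = sorted(group1 + group2)
        tie_term = 0.0
        i = 0
        while i < n:
            j = i
            while j < n and pooled[j] == pooled[i]:
                j += 1
            t = j - i
            tie_term += t**3 - t
            i = j
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 if w != mu else 0.0
            z = (abs(w - mu) - cc) / math.sqrt(var)
            p = 2.0 * float(_scipy_stats.norm.sf(z))
        p = min(1.0, p)
        method = "normal_approx"
    return GroupComparison(group1=group1, group2=group2, W=w, p_value=p, method=method)


# ---------------------------------------------------------------------------
# Grouped whole-haplotype comparison
# ---------------------------------------------------------------------------


def compare_haplotype_pair(
    ref_assembly,
    other_assembly,
    hap_by_chrom_ref: dict[int, int],
    hap_by_chrom_other: dict[int, int],
    ref_unit,
    other_unit,
    shared: bool,
    k: int = 21,
    max_gap_close: int = MAX_GAP_CLOSE,
) -> HaplotypePairComparison:
    """Align one species-labeled haplotype set against another, per chromosome."""
    variants_by_chrom: dict[int, VariantSet] = {}
    haploid = 0
    affected = 0
    for chrom in sorted(hap_by_chrom_ref):
        ref_seq = ref_assembly.sequence(chrom, hap_by_chrom_ref[chrom])
        other_seq = other_assembly.sequence(chrom, hap_by_chrom_other[chrom])
        vs = align_haplotypes(
            ref_seq, other_seq,
            ref_chrom=(chrom, hap_by_chrom_ref[chrom]),
            k=k, max_gap_close=max_gap_close,
        )
        variants_by_chrom[chrom] = vs
        haploid += len(ref_seq)
        affected += affected_union(vs, len(ref_seq))
    return HaplotypePairComparison(
        ref_unit=ref_unit,
        other_unit=other_unit,
        variants_by_chrom=variants_by_chrom,
        haploid_length=haploid,
        affected=affected,
        shared_species=shared,
    )


def grouped_similarity(
    assemblies: dict,
    labelings: dict[int, "object"],
    design,
    k: int = 21,
    max_gap_close: int = MAX_GAP_CLOSE,
):
    """All 30 directional comparisons of the six species-labeled units.

    Each unit is one genome's haplotype set assigned to one parental
    species (per-chromosome labels choose the physical haplotype).  Every
    ordered pair of distinct units is compared on the reference unit's
    coordinates — 6 shared-species and 24 non-shared comparisons for a full
    trio.  Returns ``(GroupComparison, per-pair DataFrame, comparisons)``.
    """
    units: list[tuple[str, str]] = []
    for genome in design.genomes:
        for sp in sorted(design.pedigree[genome]):
            units.append((genome, sp))
    hap_maps: dict[tuple[str, str], dict[int, int]] = {}
    for genome, sp in units:
        hap_maps[(genome, sp)] = {
            chrom: lab.unit_labeled(genome, sp)[1]
            for chrom, lab in sorted(labelings.items())
        }
    comparisons: list[HaplotypePairComparison] = []
    for ref_unit in units:
        for other_unit in units:
            if ref_unit == other_unit:
                continue
            shared = ref_unit[1] == other_unit[1]
            comparisons.append(
                compare_haplotype_pair(
                    assemblies[ref_unit[0]],
                    assemblies[other_unit[0]],
                    hap_maps[ref_unit],
                    hap_maps[other_unit],
                    ref_unit,
                    other_unit,
                    shared,
                    k=k,
                    max_gap_close=max_gap_close,
                )
            )
    shared_vals = [c.similarity_pct for c in comparisons if c.shared_species]
    nonshared_vals = [c.similarity_pct for c in comparisons if not c.shared_species]
    test = rank_sum_test(shared_vals, nonshared_vals)
    rows = []
    for c in comparisons:
        counts = c.variant_counts()
        rows.append(
            {
                "ref_genome": c.ref_unit[0],
                "ref_species": c.ref_unit[1],
                "other_genome": c.other_unit[0],
                "other_species": c.other_unit[1],
                "shared_species": c.shared_species,
                "haploid_length": c.haploid_length,
                "affected_bp": c.affected,
                "similarity_pct": c.similarity_pct,
                "n_snp": counts["SNP"],
                "n_indel": counts["INDEL"],
                "n_sv": counts["SV"],
            }
        )
    frame = pd.DataFrame(rows)
    return test, frame, comparisons
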