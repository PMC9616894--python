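"""Colinear gene-block detection between haplotypes.

Filtered best-hit anchors (identity and coverage above 80%, dual-fraction
overlap rule) are chained by dynamic programming over gene ranks: a block
is a run of at least ``match_size`` anchors whose ranks increase strictly
on the first unit and monotonically (either direction) on the second, with
at most ``max_gap`` intervening genes between consecutive anchors on both
sides.  Coverage is reported at the locus level (fraction of loci in at
least one block) and the length level (fraction of unit bp under the union
of block extents).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneLocus
from .similarity import BestHitTable

__all__ = [
    "Anchor",
    "ColinearBlock",
    "build_anchors",
    "chain_blocks",
    "block_length_coverage",
    "block_locus_coverage",
    "coverage_stats",
]

MATCH_SIZE = 10
MAX_GAP = 5
OVERLAP_WINDOW = 5


@dataclass
class Anchor:
    """A retained locus-to-locus alignment usable for chaining."""

    locus_a: GeneLocus
    locus_b: GeneLocus
    identity: float
    coverage: float

    @property
    def rank_a(self) -> int:
        return self.locus_a.rank

    @property
    def rank_b(self) -> int:
        return self.locus_b.rank


@dataclass
class ColinearBlock:
    anchors: list[Anchor]
    orientation: str  # parallel | antiparallel

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        return (
            min(a.locus_a.start for a in self.anchors),
            max(a.locus_a.end for a in self.anchors),
        )

    @property
    def span_b(self) -> tuple[int, int]:
        return (
            min(a.locus_b.start for a in self.anchors),
            max(a.locus_b.end for a in self.anchors),
        )


def build_anchors(
    hits: BestHitTable,
    chrom_index: int,
    hap_a: int,
    target_genome: str,
    hap_b: int,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    query_frac: float = 0.5,
    target_frac: float = 0.75,
) -> list[Anchor]:
    """Anchors between two units from the best-hit table.

    A hit is retained when identity and query coverage exceed the 80%
    floors and the overlap rule holds: the aligned span covers at least
    ``query_frac`` of the query locus, or the target locus covers at least
    ``target_frac`` of the aligned span (either fraction suffices).
    """
    anchors = []
    seen: set[tuple[str, str]] = set()
    for m in hits:
        if m.query.chrom_index != chrom_index or m.query.haplotype != hap_a:
            continue
        if m.target_unit != (target_genome, hap_b):
            continue
        if m.target.chrom_index != chrom_index:
            continue
        if m.identity <= min_identity or m.coverage_query <= min_coverage:
            continue
        if not (m.coverage_query >= query_frac or m.coverage_target >= target_frac):
            continue
        key = (m.query.gene_id, m.target.gene_id)
        if key in seen:
            continue
        seen.add(key)
        anchors.append(
            Anchor(
                locus_a=m.query,
                locus_b=m.target,
                identity=m.identity,
                coverage=m.coverage_query,
            )
        )
    anchors.sort(key=lambda a: (a.rank_a, a.rank_b))
    return anchors


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> list[int]:
    """Indices of the best chain in one orientation (DP, score = count).

    Ties prefer the lexicographically smallest index sequence, which makes
    the result deterministic.
    """
    n = len(anchors)
    best_len = [1] * n
    parent = [-1] * n
    for i in range(n):
        ai, bi = anchors[i].rank_a, anchors[i].rank_b
        for j in range(i):
            aj, bj = anchors[j].rank_a, anchors[j].rank_b
            if aj >= ai or ai - aj - 1 > max_gap:
                continue
            if orientation == "parallel":
                ok = bj < bi and bi - bj - 1 <= max_gap
            else:
                ok = bj > bi and bj - bi - 1 <= max_gap
            if not ok:
                continue
            if best_len[j] + 1 > best_len[i] or (
                best_len[j] + 1 == best_len[i] and parent[i] != -1 and j < parent[i]
            ):
                best_len[i] = best_len[j] + 1
                parent[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -i))
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    return chain[::-1]


def chain_blocks(
    anchors: list[Anchor],
    match_size: int = MATCH_SIZE,
    max_gap: int = MAX_GAP,
    overlap_window: int = OVERLAP_WINDOW,
) -> list[ColinearBlock]:
    """Greedy peeling of best chains into colinear blocks.

    Repeatedly extracts the highest-count valid chain over the remaining
    anchors (both orientations searched; parallel wins ties), keeps it if
    it has at least ``match_size`` anchors, and removes its anchors.
    Blocks whose rank ranges on the first unit share more than
    ``overlap_window`` anchors with a better block are dropped.
    """
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    blocks: list[ColinearBlock] = []
    while True:
        best = None
        for orientation in ("parallel", "antiparallel"):
            chain = _best_chain(remaining, orientation, max_gap)
            if best is None or len(chain) > len(best[0]):
                best = (chain, orientation)
        chain, orientation = best
        if len(chain) < match_size:
            break
        chosen = [remaining[i] for i in chain]
        blocks.append(ColinearBlock(anchors=chosen, orientation=orientation))
        chain_set = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in chain_set]
        if not remaining:
            break

    # best-kept rule for heavily overlapping blocks
    kept: list[ColinearBlock] = []
    for blk in sorted(blocks, key=lambda b: -b.n_anchors):
        lo = min(a.rank_a for a in blk.anchors)
        hi = max(a.rank_a for a in blk.anchors)
        clash = False
        for other in kept:
            inside = sum(1 for a in other.anchors if lo <= a.rank_a <= hi)
            if inside > overlap_window:
                clash = True
                break
        if not clash:
            kept.append(blk)
    kept.sort(key=lambda b: b.span_a)
    return kept


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def block_locus_coverage(blocks: list[ColinearBlock], total_loci: int) -> float:
    """Percentage of loci (both units pooled) found in at least one block."""
    if total_loci == 0:
        return 0.0
    ids = set()
    for blk in blocks:
        for a in blk.anchors:
            ids.add(("a", a.locus_a.gene_id))
            ids.add(("b", a.locus_b.gene_id))
    return 100.0 * len(ids) / total_loci


def block_length_coverage(
    blocks: list[ColinearBlock], unit_length: int, side: str = "a"
) -> float:
    """Percentage of the unit's bp covered by the union of block extents."""
    if unit_length == 0:
        return 0.0
    spans = [blk.span_a if side == "a" else blk.span_b for blk in blocks]
    return 100.0 * _interval_union(spans) / unit_length


def coverage_stats(per_pair: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Summarize per-unit-pair coverage rows into group means.

    Each row carries ``shared_species``, ``locus_pct`` and ``length_pct``
    (as produced by the pipeline); group means are reported for
    shared-species and different-species pairs, plus the overall mean
    length coverage.
    """
    frame = pd.DataFrame(per_pair)
    summary: dict[str, float] = {}
    if len(frame):
        shared = frame[frame["shared_species"]]
        nonshared = frame[~frame["shared_species"]]
        summary["locus_pct_shared"] = float(shared["locus_pct"].mean()) if len(shared) else 0.0
        summary["locus_pct_nonshared"] = (
            float(nonshared["locus_pct"].mean()) if len(nonshared) else 0.0
        )
        summary["length_pct_overall"] = float(frame["length_pct"].mean())
    else:
        summary = {
            "locus_pct_shared": 0.0,
            "locus_pct_nonshared": 0.0,
            "length_pct_overall": 0.0,
        }
    return frame, summary
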