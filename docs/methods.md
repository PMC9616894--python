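# Methods

## The shared-parentage model

Three diploid hybrid genomes form a triangle pedigree over three parental
species: each genome is a cross of two species and each species occurs in
exactly two genomes. Under correct phasing, each pseudomolecule haplotype
descends from one parental species, so for every chromosome the six
haploid units (3 genomes × 2 haplotypes) contain exactly two copies of
each species, and the three shared-species pairs are the three most
similar pairs. A haplotype switch — a phasing error that joins segments of
the two haplotypes into one pseudomolecule — breaks this pattern locally
and is visible as a change-point in which foreign haplotype a genome's
genes resemble most.

## Locus scoring

Gene loci are compared as genomic substrings (introns included; the
annotation's gene span, not the spliced transcript), minus-strand loci
reverse-complemented. Candidate pairs come from a minimizer prefilter
(k = 15, window 10, ≥ 10 shared minimizers); candidates are aligned with
edlib. The default mode is glocal: the shorter sequence aligns end-to-end
inside the longer, identity = matches / alignment block length, so
identity is symmetric in the argument order. N bases are given free
equality in the aligner so masked sequence never counts as mismatch; loci
more than half N are excluded from voting. Best hits are ranked by
identity × query coverage, ties broken by identity and then by target gene
id, and floored at 80% identity and coverage. On catalogs of up to ~100
loci the prefiltered result is identical to exhaustive all-pairs scoring
(tested over several seeds).

## Parental assignment

Per chromosome, a 6×6 matrix holds the mean best-hit identity between
every pair of units (both query directions pooled; entries with fewer than
10 supporting loci are flagged). The labeling is the orientation of the
three genomes (2³ candidates, exhaustively scored) maximizing the sum of
the three shared-species entries. A winning margin below 0.005 flags the
chromosome ambiguous; the argmax labels are still reported as provisional,
because detection does not depend on them (below) and post-correction
labelings are re-derived on clean data.

## Voting and switch detection

For a genome with pedigree species {X, Y}, each locus compares its best
hit into the partner genome sharing X (maximum identity over that
partner's two haplotypes) against its best hit into the partner sharing Y;
the larger identity wins the vote, and margins below 0.002 (or loci with
no hit on either side) vote "ambiguous". Taking the maximum over the
partner's two haplotypes makes the vote invariant to phasing errors in the
partner: a switch only moves material between a genome's haplotypes, so
the species content at each position of the partner's haplotype *pair* is
unchanged. A per-unit vote (best hit in a labeled haplotype) would be
corrupted inside the partner's switched segments; this genome-level vote
is the reason detection tolerates concurrent switches in all three
genomes.

Votes are majority-smoothed over sliding windows of 5 loci; a state change
commits when ≥ 3 consecutive smoothed votes support the new state, and the
breakpoint interval runs from the end of the last old-state raw vote to
the start of the first new-state raw vote. Events with fewer than 3
supporting raw votes on either flank are suppressed; a profile more than
half ambiguous is uncallable. Finally, events on the two haplotypes are
paired: a switch is called only where both haplotypes show change-points
with mirrored species states within 10 kbp of each other. Unpaired events
are distortions induced from outside (e.g. a partner-genome region where
both candidate units carry the third species, or vote noise) and are
dropped. The window/run/margin values are the smallest that suppressed
single-locus paralog noise in synthetic calibration; they are package
defaults, not quantities estimated from data.

## Correction

Paired events become exchange plans: per haplotype, the cut snaps to the
nearest AGP component junction *inside* the breakpoint interval (within
50 kbp), otherwise the interval midpoint. Junctions outside the intergenic
breakpoint interval are never used — cutting there would move genes whose
votes contradict the move, even if the junction is nearby. A cut not at a
junction splits the component into sub-ranges of the same contig (AGP
`component_beg`/`component_end`). Applying a plan exchanges the sequence
right of the cuts between the haplotypes, moves gene loci with their
segments (a locus spanning a cut is dropped and counted), and reassigns
components. Each exchange is an involution and conserves the
per-chromosome base multiset; haplotype lengths may change when the two
cuts differ.

## Divergence statistics

Desk-scale pairwise variant detection (inputs ≤ 10 Mbp; larger comparisons
import MUMmer `show-snps -Clr -x` / `show-diff` tables instead): k-mers of
21 bp occurring exactly once in each sequence anchor the alignment;
diagonal runs are merged and chained by longest increasing subsequence on
both coordinates. Inter-anchor gaps are closed exactly — equal-length gaps
≤ 30 bp by direct base comparison, others by edlib global alignment — when
both sides are ≤ 20 kbp; larger gaps are emitted as SV spans, as is any
unanchored sequence. Variants classify as SNP (1 bp substitution), INDEL
(≤ 50 bp) or SV (> 50 bp) by the larger of reference span and alternate
length. A pure insertion affects one junction base on the reference; a
paired insertion+deletion inside one small equal-length gap is scored as
substitutions. The unaffected-length similarity is
100 × (1 − affected/haploid length) with affected spans unioned
(overlaps counted once), aggregated over the chromosome set; unaligned
reference sequence counts as affected (conservative: it cannot be called
unaffected). Both directions of every unit pair are computed and reported
separately, never averaged.

The six species-labeled units yield 30 directional comparisons (6 shared-
species, 24 non-shared, including the intra-genome pairs, which are always
non-shared). The rank-sum test uses W = #{(x, y): x > y} + ½·ties; for
n₁ + n₂ ≤ 20 the two-sided p is exact by enumeration over all assignments
of the pooled values (ties handled by direct pair counting — identical
groups give p = 1), otherwise a normal approximation with tie and
continuity corrections. For the 6-vs-24 design, W = 142 gives
z = (142 − 72 − 0.5)/√372 = 3.60 and two-sided p ≈ 3.1 × 10⁻⁴.

## Colinearity

Anchors are best hits with identity and query coverage above 80% that
additionally satisfy a dual-fraction overlap rule (aligned span ≥ 50% of
the query locus, or target locus ≥ 75% of the aligned span; either
suffices). Chaining is dynamic programming over gene ranks: strictly
increasing on the first unit, strictly monotone (either direction) on the
second, at most 5 intervening genes between consecutive anchors on both
sides, chain score = anchor count. Blocks of ≥ 10 anchors are peeled off
greedily (ties prefer the parallel orientation and the lexicographically
smallest chain); blocks sharing more than 5 anchors' worth of rank range
with a better block are dropped. Locus coverage is the percentage of loci
(both units pooled) in at least one block; length coverage the percentage
of unit bp under the union of block extents.

## The synthetic generator

The generator *is* the study design, not a tuning surface. Defaults:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 2 × 500 kbp | desk-scale stand-in for 19 × ~26 Mbp |
| genes per chromosome | 200 (1 kbp each) | enough vote density per segment |
| sister-species SNP rate | 0.02 /bp | few-percent interspecies divergence |
| sister-species indel rate | 0.004 /bp (≤ 10 bp) | indels ≈ ⅕ of SNPs |
| SVs per chromosome | 5, 100–2000 bp | exercises the > 50 bp class |
| third-species rate scale | 1.5 | three distinct pairwise divergences |
| within-species haplotype noise | 0.2 × sister rates | shared-species similarity exceeds cross-species by construction |
| switches per genome | 5 | several per chromosome, alternating states |
| switch separation | ≥ 8 mean gene intervals | each exchanged segment carries enough votes to be resolvable by a window-5/min-run-3 detector |

Species B and C derive from species A by independent mutation passes; gene
loci are lifted through every edit, with short indels forbidden from
crossing gene boundaries and SVs (deletions and tandem duplications)
placed wholly intergenic so every ortholog survives. Haplotypes are fresh
low-rate mutation passes over their parental species sequence. Pseudomolecules
are cut into 2–6 AGP components; injected switches exchange the suffix at
a breakpoint sampled from component junctions with probability 0.8 (else
uniform), restricted to positions intergenic on both haplotypes. One numpy
Generator seeded once drives all sampling; identical seeds give
byte-identical FASTA.

What the generator does **not** emulate: repeat landscapes and segmental
duplication (so paralog confusion is milder than in real genomes), gaps
and N runs, assembly base errors, inversions/translocations between
haplotypes, unplaced sequence with genes, and real gene structure
(UTRs/introns are not modeled separately). Passing tests therefore
demonstrate the pipeline's logic and calibration under clean colinear
divergence, not performance on repeat-rich real assemblies — there, the
external-alignment import paths (PAF, MUMmer tables) carry the heavy
alignment work.

## Numerical and design choices

- All internal coordinates are 0-based half-open; GFF3/AGP conversion
  happens only at I/O boundaries. Emitted outputs are byte-deterministic.
- Rank ties in catalogs break by gene id; best-hit ties by identity then
  target id; labeling enumeration is exhaustive so needs no tie policy
  beyond score order.
- The locus scorer is self-contained (prefilter + edlib) rather than a
  wrapper around an external long-read mapper, so it is oracle-testable;
  externally produced PAF can replace it at real scale.
- Coordinate drift between haplotypes (indels/SVs shift positions by up to
  a few kbp) means a cut at the same position on both haplotypes can
  exchange slightly different gene sets; the chromosome *pair* conserves
  both copies of every ortholog, which is the invariant the tests assert.
- Problem sizes in the test suite: unit tests run on 1–2 chromosomes of
  40–120 kbp; acceptance tests on the full default study (2 × 500 kbp,
  10 seeds for detection). The acceptance script pools detection over 3
  seeds and runs one full end-to-end analysis.

## Known limitations

- Switches shorter than ~5 gene loci are below the detector's designed
  resolution (window 5, min-run 3) and are not called.
- The anchor-chain aligner assumes colinear haplotypes; a large inversion
  would be emitted as one SV span, not aligned internally.
- Insertions relative to the reference contribute one affected bp, so the
  directional similarity of a unit against a much longer partner is
  slightly higher than the reverse direction.
- Correction applies plans in coordinate order; when multiple switches on
  one chromosome have *different* cut offsets between the haplotypes,
  later cut coordinates can drift by the accumulated offset difference
  (truth-derived and junction-snapped plans have equal cuts and are
  unaffected).
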