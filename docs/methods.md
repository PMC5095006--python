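# Methods

## Detection model

A circular RNA leaves exactly one short-read signature: fragments consistent
with a head-to-tail (backspliced) junction between a downstream exon (Exon2)
and an upstream exon (Exon1) of the same gene. `circkit` enumerates the full
sample space of such junctions from the annotation — every intragenic exon
pair with `rank(exon1) ≤ rank(exon2)`, including the single-exon self-join —
and builds one reference entry per pair: the transcribed-orientation sequence
of exon2 followed by exon1. Exons are collapsed per gene across transcripts
(unique genomic intervals), because the junction space is a property of the
gene's exon set, not of any particular isoform. Coordinates are 0-based
half-open internally; GTF input (1-based inclusive) is converted on load.

Entries carry the full concatenated exon sequences rather than a fixed window
around the junction, so a non-spanning mate can rest anywhere on either exon
and still anchor its pair to a single alignment target. Single-exon entries
duplicate the exon (seq+seq) so a junction-spanning read aligns contiguously.

### Evidence classes

Given a primary, deduplicated fragment on an entry with junction offset `o`:

* **junctional** — some mate covers `o` with at least `min_overlap` (default
  10) bases on each side. A spanning mate trivially overlaps one exon, so the
  anchored-on-both-sides reading is the only non-vacuous interpretation of a
  minimum-overlap rule.
* **supportive** — no mate achieves the anchored crossing, but the fragment's
  outer span covers `o` in concordant FR orientation on the entry. On the
  genome these mates point away from each other (divergent), a layout only a
  circular template produces. This includes mates that touch the junction with
  sub-threshold (< 10 bp) overlap: the fragment still demonstrably crosses the
  backsplice point, it just lacks a well-anchored junction read.
* **none** — both mates on one side of `o`: indistinguishable from the linear
  transcript, never counted.

A fragment counted as junctional is never also counted as supportive.

### Calling thresholds

A junction becomes a candidate when, in at least one sample, it accumulates
≥ 3 distinct junctional fragments, or enough supporting fragments under the
configured policy: **policy A** (default) requires junctional + supportive
≥ 10; **policy B** requires ≥ 10 strictly supportive fragments. The supported
threshold is genuinely ambiguous — known single-exon circles can be abundant
in supportive evidence while lacking junctional reads entirely, which argues
for assessing the supportive route independently — so both policies are
implemented and tested; A is the default because a junctional fragment is
strictly stronger evidence than a supportive one and discarding it from the
total would be perverse. Candidates are reported per sample and as the
cross-sample union, in genomic-coordinate order.

### Negative controls

Two control references are built by the same code path and run through the
identical pipeline: `randomized` shuffles each distinct exon's sequence once
(seeded; composition, entry count and lengths preserved), destroying real
sequence so that any surviving candidate measures alignment artifacts;
`flipped_exon2` concatenates exon1 with the reverse complement of exon2
(head-to-head junction, offset = exon1 length), probing sequence-redundancy
artifacts without randomization. The control report counts control candidates
and their junction-id intersection with the real candidate set.

## Built-in mapper

Junction entries are purely exonic and the target reads are ~50 bp, so an
ungapped k-mer seed-and-extend mapper (k = 15, seeds at stride k plus the
final position, mismatch ceiling 2 per mate) suffices to exercise the whole
pipeline without an external aligner; with three disjoint seeds per 50 bp
read and ceiling 2, at least one seed is always exact, so no valid placement
is missed. Pairs must be FR, inward-facing, on one entry, within a span cap
(default 1000). The best placement minimizes total mismatches with ties broken
by (entry id, forward start, reverse start) — fully deterministic. SAM/BAM
import (primary records only, 0x100/0x800 dropped) is the production path, and
the built-in mapper exports SAM that round-trips through the importer.

Duplicate removal follows positional semantics: fragments sharing (sample,
entry, outer start, outer end, mate orientation) collapse to the
lexicographically smallest fragment id, making the survivor set independent of
input order.

## Quantification

* circRNA expression per junction/sample = count of distinct junctional +
  supportive fragments.
* Linear expression for the same exon pair counts concordant FR genome
  fragments overlapping either exon by ≥ 1 base (each fragment once per
  junction, divergent pairs excluded). Exon-internal reads cannot be assigned
  to one form, so they are all credited to the linear form — the
  circular:linear ratio is therefore a conservative lower bound on circular
  usage. Ratio sentinels: linear = 0 with circ > 0 reports `circ_only` (inf);
  both zero drops the row.
* FPKM = count / (length/10³) / (mapped/10⁶). Fold-change enrichment adds a
  1-fragment pseudocount before the FPKM transform (negligible at high
  counts), restricts the mRNA universe to genes with a detected circular
  isoform when given, and compares circ vs mRNA fold-change distributions
  with a one-sided Mann-Whitney test.
* Prefilter keeps rows with ≥ 3 counts in ≥ 3 samples (idempotent). Heatmap
  transform: per-row z-score of log2(CPM + 0.5); constant rows map to 0.

## Simulator

The generator is the package's study-condition definition, not a tuning dial:

* **Genome fixture**: 50 genes (default) on one synthetic chromosome, random
  strands, 3–8 exons of 70–120 bp, introns 60–200 bp, uniform base
  composition, fully determined by the seed.
* **Circles**: n (default 200) junctions drawn uniformly without replacement.
  The circular sequence is the entry (exon2+exon1) treated as circular —
  fragment start positions wrap modulo its length — matching the observation
  that sequenced circles correspond to the spliced exons with only the
  circularization added; interior-exon inclusion for distant pairs is out of
  scope.
* **Reads**: 50 bp mates; fragment length Normal(85, 8) truncated at the read
  length (mates overlap, as in short-insert libraries); i.i.d. substitution
  errors (default 1%); the forward/reverse role of read1 is random; linear
  background fragments are drawn from each gene's spliced transcript (default
  30 per gene). Depth is **fragments per circle** — the unambiguous desk-scale
  analogue of expression level — not per-base coverage.

The fragment-length default is deliberately matched to the two-exon circle
model. A fragment only carries backsplice evidence if it both covers the
junction point and fits the linearized entry: a fragment crossing the circle's
canonical-splice point is sequence-identical to a linear fragment and is
correctly rejected. For a circle of length L the junctional window is
2·(50 − 2·10 + 1) = 62 of L start positions, and an anchored mate needs the
flanking exon to be at least (fragment − 40) bp, so fragments much longer than
the shorter exon silently destroy the junctional signal. With exons 70–120 bp
and fragments ~85 bp the expected junctional count at 20 fragments/circle is
about 20·62/L ≈ 5–8, which is what makes the depth-20 benchmark informative
rather than saturated or hopeless. With human-scale multi-exon circles and
conventional ~200 bp inserts the same geometry holds with all lengths scaled
up; the short-insert choice is the faithful miniature, and is stated here
once as the package's study condition.

What the simulator does **not** model: base-quality-dependent errors, indels
(the mapper is ungapped by design), PCR duplication beyond exact copies,
fragment-level GC bias, multi-exon circle interiors, and RNase-R kinetics
(modeled as a plain linear-depletion factor in `simulate_rnase_r_counts`).
Passing benchmarks therefore demonstrate the correctness of the detection
logic and its thresholds under clean geometry, not performance on degraded
libraries or unannotated junctions.

Evaluation is set algebra on junction ids: TP = called ∩ truth,
FP = called \ truth, FN = truth \ called; sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), with undefined rates flagged rather than coerced to
zero. TP+FN = |truth| and TP+FP = |called| hold identically.

## Sponge scoring

Seed sites use the canonical definitions (target 5′→3′): 8mer =
revcomp(miRNA 2–8) + A, 7mer-m8 = revcomp(2–8), 7mer-A1 = revcomp(2–7) + A;
each target position reports its strongest type, overlapping sites at
different positions are all reported, windows containing N are skipped, and
U/T and case are normalized. circRNA targets may be scanned circularly
(the window wraps across the backsplice seam). Density = sites × 1000 /
length, with per-class tables and an empirical CDF helper for circ vs
3′UTR/5′UTR/CDS comparisons.

E_circ for miRNA-x is the exact arithmetic mean of n_xi·x_i over the N
circRNAs with sites for x (edges with zero sites are excluded from N);
Average E_circ per gene is the mean of E_circ over the gene's targeting
miRNAs, with the miRNA→gene edge table supplied externally (target prediction
is out of scope). x_i is taken as log2 fold change from an upstream
differential-expression table: the statistic is linear in x, so the choice of
scale affects interpretation, not mechanics; log2 keeps up- and
down-regulation symmetric around 0. Context+ scoring and thermodynamic
(cofold) filtering are not reimplemented; a pass-through column lets
externally computed scores filter matches.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeds recorded in
  outputs; identical configuration produces byte-identical artifacts.
* The provenance hash covers analytic settings only (not output paths).
* Tie-breaks (mapper placements, duplicate survivors, candidate order) are
  lexicographic and documented, so no output depends on dict/set iteration
  order.
* Degenerate inputs: genes with zero exons are skipped with a warning; a
  missing chromosome is a hard error naming it; alignments off an entry are a
  hard (caller-bug) error; zero mapped totals and zero-length features are
  hard errors in FPKM; empty evidence sets produce empty candidate lists, not
  exceptions.
* Benchmark sizes (50 genes ≈ 1000 junctions, 200 circles, depths ≤ 20, five
  seeds) were chosen so the full simulation study runs in seconds on one CPU
  while keeping ≥ 200 Bernoulli trials behind every rate estimate.

## Known limitations

Only annotation-derived junctions are discoverable (no de novo, intergenic,
or intron-retaining circles). The linear count is exon-pair-level, not
isoform-resolved. The built-in mapper is intentionally minimal — ungapped, no
base qualities — and external aligner output should be preferred on real
data. Differential expression (TMM normalization, NB GLMs, FDR control) is
exported as plain TSV count matrices for edgeR/DESeq2-class tools rather than
reimplemented.
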