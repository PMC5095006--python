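"""Placement of paired-end fragments on the junction reference.

Two routes produce :class:`~circkit.models.ReadPairAlignment` streams:

* :func:`import_alignments` — the production path; reads SAM/BAM produced by an
  external aligner against the junction FASTA, keeping only primary,
  fully-paired records.
* :class:`KmerIndex` + :func:`map_pair` — a built-in ungapped k-mer
  seed-and-extend mapper, so the whole pipeline is testable without an external
  aligner. Junction entries are purely exonic and reads are short (~50 bp), so
  ungapped placement with a small mismatch ceiling suffices; the evidence rules
  downstream, not the aligner, carry the method's logic.

Duplicate removal follows positional (samtools-rmdup-style) semantics: fragments
sharing reference entry, outer coordinates and orientation collapse to one
representative.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from circkit.models import JunctionEntry, ReadPairAlignment
from circkit.sequtils import revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MAX_SPAN = 1000


class KmerIndex:
    """Exact-match k-mer index over junction entries."""

    def __init__(self, entries: Sequence[JunctionEntry], k: int = DEFAULT_K):
        self.k = k
        self.entries: dict[str, JunctionEntry] = {e.junction_id: e for e in entries}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for e in entries:
            seq = e.sequence
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((e.junction_id, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _mismatches(query: str, target: str, start: int, ceiling: int) -> int:
    """Count mismatches of query vs target[start:start+len(query)], abort past ceiling."""
    n = 0
    for i, c in enumerate(query):
        if target[start + i] != c:
            n += 1
            if n > ceiling:
                return n
    return n


def _candidate_placements(
    read: str, index: KmerIndex, max_mismatch: int
) -> dict[tuple[str, int, str], int]:
    """All ungapped placements of a read (either strand) within the mismatch ceiling.

    Seeds are taken at stride k plus the final position; with ceiling 2 and
    three or more disjoint seeds at least one seed is mismatch-free, so no
    valid placement is missed for typical 50 bp reads.
    """
    k = index.k
    placements: dict[tuple[str, int, str], int] = {}
    for strand in ("+", "-"):
        q = read if strand == "+" else revcomp(read)
        if len(q) < k:
            continue
        seed_offsets = list(range(0, len(q) - k + 1, k))
        if seed_offsets[-1] != len(q) - k:
            seed_offsets.append(len(q) - k)
        seen: set[tuple[str, int]] = set()
        for off in seed_offsets:
            for entry_id, pos in index.lookup(q[off : off + k]):
                start = pos - off
                if start < 0:
                    continue
                entry = index.entries[entry_id]
                if start + len(q) > entry.length:
                    continue
                key = (entry_id, start)
                if key in seen:
                    continue
                seen.add(key)
                nm = _mismatches(q, entry.sequence, start, max_mismatch)
                if nm <= max_mismatch:
                    placements[(entry_id, start, strand)] = nm
    return placements


def map_pair(
    read1: str,
    read2: str,
    index: KmerIndex,
    fragment_id: str = "frag",
    sample_id: str = "sample1",
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_fragment_span: int = DEFAULT_MAX_SPAN,
) -> ReadPairAlignment | None:
    """Best concordant (FR, inward-facing) placement of a pair on one entry.

    The winner minimizes total mismatches; ties break on (entry_id, forward
    start, reverse start) so output is deterministic. Returns None when no
    placement satisfies the orientation, span and mismatch constraints.
    """
    p1 = _candidate_placements(read1, index, max_mismatch)
    p2 = _candidate_placements(read2, index, max_mismatch)
    if not p1 or not p2:
        return None

    by_entry_1: dict[str, list[tuple[int, str, int]]] = defaultdict(list)
    for (entry_id, start, strand), nm in p1.items():
        by_entry_1[entry_id].append((start, strand, nm))
    best: tuple | None = None
    for (entry_id, s2, strand2), nm2 in p2.items():
        for s1, strand1, nm1 in by_entry_1.get(entry_id, []):
            if strand1 == strand2:
                continue  # FR requires opposite strands
            if strand1 == "+":
                fwd_start, rev_start = s1, s2
                rev_end = s2 + len(read2)
            else:
                fwd_start, rev_start = s2, s1
                rev_end = s1 + len(read1)
            if fwd_start > rev_start:
                continue  # outward-facing on the entry
            if rev_end - fwd_start > max_fragment_span:
                continue
            key = (nm1 + nm2, entry_id, fwd_start, rev_start, strand1)
            cand = (key, entry_id, s1, strand1, nm1, s2, strand2, nm2)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return None
    _, entry_id, s1, strand1, nm1, s2, strand2, nm2 = best
    return ReadPairAlignment(
        fragment_id=fragment_id,
        entry_id=entry_id,
        m1_start=s1,
        m1_end=s1 + len(read1),
        m2_start=s2,
        m2_end=s2 + len(read2),
        m1_strand=strand1,
        m2_strand=strand2,
        primary=True,
        n_mismatch=nm1 + nm2,
        sample_id=sample_id,
    )


def map_pairs(
    pairs: Iterable[tuple[str, str, str]],
    index: KmerIndex,
    sample_id: str = "sample1",
    **kwargs,
) -> list[ReadPairAlignment]:
    """Map an iterable of (fragment_id, read1, read2); unmappable pairs dropped."""
    out = []
    for fragment_id, r1, r2 in pairs:
        aln = map_pair(r1, r2, index, fragment_id=fragment_id, sample_id=sample_id, **kwargs)
        if aln is not None:
            out.append(aln)
    return out


def map_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    index: KmerIndex,
    sample_id: str = "sample1",
    **kwargs,
) -> list[ReadPairAlignment]:
    """Map mate FASTQ files (records in lockstep) with the built-in mapper."""
    pairs = []
    with pysam.FastxFile(str(fastq1)) as f1, pysam.FastxFile(str(fastq2)) as f2:
        for r1, r2 in zip(f1, f2):
            name = r1.name
            for suffix in ("/1", "/2"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
            pairs.append((name, r1.sequence.upper(), r2.sequence.upper()))
    return map_pairs(pairs, index, sample_id=sample_id, **kwargs)


def export_sam(
    alignments: Iterable[ReadPairAlignment],
    entries: Sequence[JunctionEntry],
    path: str | Path,
) -> None:
    """Write alignments as SAM against the junction reference."""
    entries = sorted(entries, key=lambda e: e.junction_id)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": e.junction_id, "LN": e.length} for e in entries],
    }
    tid = {e.junction_id: i for i, e in enumerate(entries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            for mate_idx in (1, 2):
                a = pysam.AlignedSegment(out.header)
                a.query_name = aln.fragment_id
                a.reference_id = tid[aln.entry_id]
                start = aln.m1_start if mate_idx == 1 else aln.m2_start
                end = aln.m1_end if mate_idx == 1 else aln.m2_end
                strand = aln.m1_strand if mate_idx == 1 else aln.m2_strand
                o_start = aln.m2_start if mate_idx == 1 else aln.m1_start
                o_strand = aln.m2_strand if mate_idx == 1 else aln.m1_strand
                a.reference_start = start
                a.cigarstring = f"{end - start}M"
                flag = 0x1 | 0x2
                flag |= 0x40 if mate_idx == 1 else 0x80
                if strand == "-":
                    flag |= 0x10
                if o_strand == "-":
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = tid[aln.entry_id]
                a.next_reference_start = o_start
                a.template_length = 0
                a.mapping_quality = 60
                a.set_tag("NM", aln.n_mismatch)
                out.write(a)


def import_alignments(
    path: str | Path,
    known_entries: set[str] | None = None,
    sample_id: str = "sample1",
) -> list[ReadPairAlignment]:
    """Import paired primary alignments from SAM/BAM.

    Secondary (0x100) and supplementary (0x800) records are dropped — only the
    primary alignments are kept — as are unpaired or half-mapped fragments and
    mates landing on different references. Records naming a reference outside
    ``known_entries`` (when given) are logged and skipped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    mates: dict[str, dict[int, pysam.AlignedSegment]] = defaultdict(dict)
    n_skipped_ref = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if known_entries is not None and rec.reference_name not in known_entries:
                n_skipped_ref += 1
                continue
            mate_idx = 1 if rec.is_read1 else 2
            mates[rec.query_name][mate_idx] = rec
    if n_skipped_ref:
        logger.warning("skipped %d records with unknown reference names", n_skipped_ref)

    out = []
    for name in sorted(mates):
        pair = mates[name]
        if 1 not in pair or 2 not in pair:
            continue
        r1, r2 = pair[1], pair[2]
        if r1.reference_name != r2.reference_name:
            continue
        nm = 0
        for r in (r1, r2):
            if r.has_tag("NM"):
                nm += r.get_tag("NM")
        out.append(
            ReadPairAlignment(
                fragment_id=name,
                entry_id=r1.reference_name,
                m1_start=r1.reference_start,
                m1_end=r1.reference_end,
                m2_start=r2.reference_start,
                m2_end=r2.reference_end,
                m1_strand="-" if r1.is_reverse else "+",
                m2_strand="-" if r2.is_reverse else "+",
                primary=True,
                n_mismatch=nm,
                sample_id=sample_id,
            )
        )
    return out


def remove_duplicates(alignments: Iterable[ReadPairAlignment]) -> list[ReadPairAlignment]:
    """Collapse positional duplicates per sample (rmdup semantics).

    Fragments sharing (sample, entry, outer start, outer end, mate orientation)
    keep one representative: the lexicographically smallest fragment_id, making
    the survivor set independent of input order.
    """
    groups: dict[tuple, ReadPairAlignment] = {}
    n_in = 0
    for aln in alignments:
        n_in += 1
        key = (
            aln.sample_id,
            aln.entry_id,
            aln.outer_start,
            aln.outer_end,
            aln.m1_strand,
            aln.m2_strand,
        )
        kept = groups.get(key)
        if kept is None or aln.fragment_id < kept.fragment_id:
            groups[key] = aln
    survivors = sorted(groups.values(), key=lambda a: (a.sample_id, a.entry_id, a.outer_start, a.fragment_id))
    n_dup = n_in - len(survivors)
    if n_dup:
        logger.info("removed %d positional duplicates (%d fragments kept)", n_dup, len(survivors))
    return survivors
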