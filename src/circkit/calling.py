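"""Evidence classification and circRNA candidate calling.

A deduplicated fragment on a junction entry is classified as:

* ``junctional`` — one mate crosses the backsplice point with at least
  ``min_overlap`` (default 10) bases anchored on each exon, the other mate
  resting anywhere on the entry;
* ``supportive`` — no mate achieves that anchored crossing, but the fragment's
  outer span covers the backsplice point in concordant FR orientation on the
  entry (equivalently, the mates are divergent on the genome — a layout only a
  circular template produces);
* ``none`` — both mates sit on one side of the junction, indistinguishable
  from a linear transcript.

A junction becomes a candidate circRNA when it accumulates at least
``min_junctional`` (default 3) distinct junctional fragments, or enough
supporting fragments (default 10) under the configured policy:

* policy A (default): junctional + supportive fragments together >= 10;
* policy B: strictly supportive fragments alone >= 10.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from circkit.models import CandidateCircRNA, EvidenceClass, JunctionEntry, ReadPairAlignment

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MIN_JUNCTIONAL = 3
DEFAULT_MIN_SUPPORTED = 10


def classify_pair(
    aln: ReadPairAlignment,
    entry: JunctionEntry,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EvidenceClass:
    """Classify one fragment against the junction entry it aligned to."""
    L = entry.length
    for s, e in ((aln.m1_start, aln.m1_end), (aln.m2_start, aln.m2_end)):
        if s < 0 or e > L:
            raise ValueError(
                f"alignment {aln.fragment_id} [{s},{e}) outside entry {entry.junction_id} of length {L}"
            )
    off = entry.junction_offset

    best_left = best_right = 0
    for s, e in ((aln.m1_start, aln.m1_end), (aln.m2_start, aln.m2_end)):
        if s < off < e:
            left, right = off - s, e - off
            if min(left, right) >= min_overlap and min(left, right) > min(best_left, best_right):
                best_left, best_right = left, right
    if min(best_left, best_right) >= min_overlap:
        return EvidenceClass(
            fragment_id=aln.fragment_id,
            junction_id=entry.junction_id,
            evidence="junctional",
            overlap_left=best_left,
            overlap_right=best_right,
            sample_id=aln.sample_id,
        )

    if aln.outer_start < off < aln.outer_end:
        return EvidenceClass(
            fragment_id=aln.fragment_id,
            junction_id=entry.junction_id,
            evidence="supportive",
            sample_id=aln.sample_id,
        )

    return EvidenceClass(
        fragment_id=aln.fragment_id,
        junction_id=entry.junction_id,
        evidence="none",
        sample_id=aln.sample_id,
    )


def classify_alignments(
    alignments: Iterable[ReadPairAlignment],
    entries: Mapping[str, JunctionEntry] | Sequence[JunctionEntry],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[EvidenceClass]:
    """Classify every alignment; alignments to unknown entries raise."""
    if not isinstance(entries, Mapping):
        entries = {e.junction_id: e for e in entries}
    return [classify_pair(aln, entries[aln.entry_id], min_overlap) for aln in alignments]


def call_candidates(
    evidence: Iterable[EvidenceClass],
    entries: Mapping[str, JunctionEntry] | Sequence[JunctionEntry],
    min_junctional: int = DEFAULT_MIN_JUNCTIONAL,
    min_supported: int = DEFAULT_MIN_SUPPORTED,
    policy: str = "A",
) -> list[CandidateCircRNA]:
    """Aggregate evidence into candidates with per-sample counts and pass flags.

    Counts are of distinct fragments (the input must already be deduplicated);
    a fragment counted as junctional never also counts as supportive. Each
    candidate records which samples individually pass, and ``passed`` is the
    union across samples. Output is ordered by genomic coordinate.
    """
    if policy not in ("A", "B"):
        raise ValueError(f"unknown policy {policy!r}; expected 'A' or 'B'")
    if not isinstance(entries, Mapping):
        entries = {e.junction_id: e for e in entries}

    junc: dict[tuple[str, str], set[str]] = defaultdict(set)
    supp: dict[tuple[str, str], set[str]] = defaultdict(set)
    for ev in evidence:
        if ev.evidence == "junctional":
            junc[(ev.junction_id, ev.sample_id)].add(ev.fragment_id)
        elif ev.evidence == "supportive":
            supp[(ev.junction_id, ev.sample_id)].add(ev.fragment_id)

    per_junction: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)
    for (jid, sample), frags in junc.items():
        per_junction[jid][sample] = (len(frags), 0)
    for (jid, sample), frags in supp.items():
        # a fragment contributing junctional evidence is not double-counted
        frags = frags - junc.get((jid, sample), set())
        j, _ = per_junction[jid].get(sample, (0, 0))
        per_junction[jid][sample] = (j, len(frags))

    def passes(j: int, s: int) -> bool:
        if j >= min_junctional:
            return True
        if policy == "A":
            return j + s >= min_supported
        return s >= min_supported

    candidates = []
    for jid, samples in per_junction.items():
        entry = entries[jid]
        passed_samples = sorted(s for s, (j, sup) in samples.items() if passes(j, sup))
        candidates.append(
            CandidateCircRNA(
                junction_id=jid,
                gene_id=entry.gene_id,
                chrom=entry.chrom,
                e1_start=entry.e1_start,
                e2_end=entry.e2_end,
                strand=entry.strand,
                junctional_count={s: j for s, (j, _) in samples.items()},
                supported_count={s: sup for s, (_, sup) in samples.items()},
                passed_samples=passed_samples,
                passed=bool(passed_samples),
            )
        )
    candidates.sort(key=lambda c: (c.chrom, c.e1_start, c.e2_end, c.junction_id))
    return candidates


def passed_junctions(candidates: Iterable[CandidateCircRNA]) -> set[str]:
    return {c.junction_id for c in candidates if c.passed}


def run_control(
    control_alignments: Iterable[ReadPairAlignment],
    control_entries: Sequence[JunctionEntry],
    real_candidates: Iterable[CandidateCircRNA],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_junctional: int = DEFAULT_MIN_JUNCTIONAL,
    min_supported: int = DEFAULT_MIN_SUPPORTED,
    policy: str = "A",
) -> tuple[list[CandidateCircRNA], dict]:
    """Run the identical calling logic on a negative-control reference.

    Returns the control candidate list and a report with the control candidate
    count and its junction_id intersection with the real candidate set.
    """
    from circkit.mapping import remove_duplicates

    deduped = remove_duplicates(control_alignments)
    ev = classify_alignments(deduped, control_entries, min_overlap)
    control_candidates = call_candidates(
        ev, control_entries, min_junctional, min_supported, policy
    )
    control_ids = passed_junctions(control_candidates)
    real_ids = passed_junctions(real_candidates)
    overlap = sorted(control_ids & real_ids)
    report = {
        "n_control_candidates": len(control_ids),
        "n_real_candidates": len(real_ids),
        "n_overlap": len(overlap),
        "overlap_junctions": overlap,
    }
    return control_candidates, report


def write_candidates(
    candidates: Sequence[CandidateCircRNA],
    path: str | Path,
    provenance: str | None = None,
) -> None:
    """BED-like TSV: coordinates 0-based half-open, aggregate + per-sample counts."""
    samples = sorted({s for c in candidates for s in c.junctional_count} |
                     {s for c in candidates for s in c.supported_count})
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        cols = ["chrom", "e1_start", "e2_end", "junction_id", "junctional_count", "strand",
                "supported_count", "gene_id", "passed", "passed_samples"]
        for s in samples:
            cols += [f"junctional_{s}", f"supported_{s}"]
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [c.chrom, str(c.e1_start), str(c.e2_end), c.junction_id,
                   str(c.total_junctional()), c.strand, str(c.total_supported()),
                   c.gene_id, str(int(c.passed)), ",".join(c.passed_samples) or "."]
            for s in samples:
                row += [str(c.junctional_count.get(s, 0)), str(c.supported_count.get(s, 0))]
            fh.write("\t".join(row) + "\n")
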