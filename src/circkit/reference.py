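"""Scrambled-exome reference construction.

A circular RNA is diagnosed by a head-to-tail ("backspliced") junction in which
the 3' end of a downstream exon (Exon2) is joined to the 5' start of an
upstream exon (Exon1). The sample space of such junctions for an annotated
genome is every intragenic exon pair (exon1.rank <= exon2.rank, including the
single-exon self-join). This module enumerates those pairs and materializes one
reference entry per pair: the transcribed-orientation sequence of exon2
followed by exon1, with the junction offset recorded so downstream code can ask
whether a read crosses the backsplice point.

Two negative-control variants of the reference are also built:

* ``randomized`` — each exon's sequence is independently shuffled (base
  composition preserved), destroying real sequence while keeping entry counts
  and lengths identical; reads should find no junction here.
* ``flipped_exon2`` — head-to-head entries (exon1 + reverse-complemented
  exon2), probing alignment artifacts from sequence redundancy rather than
  randomness.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from circkit.models import BacksplicePair, Exon, GeneModel, JunctionEntry
from circkit.sequtils import revcomp

logger = logging.getLogger(__name__)

CONTROL_MODES = ("randomized", "flipped_exon2")


def load_annotation(annotation_path: str | Path, genome_path: str | Path) -> list[GeneModel]:
    """Parse a GTF/GFF3 annotation into per-gene collapsed exon models.

    Exons are deduplicated across transcripts by (start, end), converted to
    0-based half-open coordinates, and ranked 5'->3' in transcribed direction
    (reverse of genomic order on the minus strand).

    Raises ``ValueError`` naming the chromosome if the annotation references a
    sequence absent from the genome FASTA. Genes with zero exon records are
    skipped with a warning.
    """
    import gffutils

    genome = Fasta(str(genome_path))
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_gene: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            parents = [p.id for p in db.parents(feat, featuretype="gene")]
            gene_ids = parents or [feat.attributes.get("Parent", ["?"])[0]]
        per_gene.setdefault(gene_ids[0], []).append(feat)

    # genes annotated but with no exon children
    for feat in db.features_of_type("gene"):
        per_gene.setdefault(feat.id, [])

    models: list[GeneModel] = []
    for gene_id in sorted(per_gene):
        feats = per_gene[gene_id]
        if not feats:
            logger.warning("gene %s has no exon records; skipped", gene_id)
            continue
        chrom = feats[0].seqid
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} referenced by gene {gene_id} missing from genome FASTA")
        strand = feats[0].strand
        coords = sorted({(f.start - 1, f.end) for f in feats})  # GTF 1-based incl -> 0-based half-open
        if strand == "-":
            coords = coords[::-1]
        exons = [
            Exon(gene_id=gene_id, chrom=chrom, start=s, end=e, strand=strand, rank=i + 1)
            for i, (s, e) in enumerate(coords)
        ]
        models.append(GeneModel(gene_id=gene_id, exons=exons))
    return models


def enumerate_backsplices(gene: GeneModel) -> list[BacksplicePair]:
    """All intragenic backsplice pairs of a gene: n(n+1)/2 for n exons.

    Ordered deterministically by (exon1.rank, exon2.rank). exon1.rank ==
    exon2.rank is the single-exon backsplice.
    """
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    pairs = []
    for e1 in gene.exons:
        for e2 in gene.exons:
            if e1.rank <= e2.rank:
                pairs.append(BacksplicePair(gene_id=gene.gene_id, exon1=e1, exon2=e2))
    return pairs


def _exon_seq(exon: Exon, genome: Fasta) -> str:
    """Transcribed-orientation sequence of an exon (revcomp on minus strand)."""
    chrom_len = len(genome[exon.chrom])
    if exon.end > chrom_len:
        raise ValueError(
            f"exon {exon.gene_id} [{exon.start},{exon.end}) exceeds {exon.chrom} length {chrom_len}"
        )
    seq = str(genome[exon.chrom][exon.start : exon.end]).upper()
    return revcomp(seq) if exon.strand == "-" else seq


def _entry_from_pair(pair: BacksplicePair, seq1: str, seq2: str) -> JunctionEntry:
    return JunctionEntry(
        junction_id=pair.junction_id,
        sequence=seq2 + seq1,
        junction_offset=len(seq2),
        exon1_len=len(seq1),
        exon2_len=len(seq2),
        chrom=pair.exon1.chrom,
        e1_start=pair.exon1.start,
        e1_end=pair.exon1.end,
        e2_start=pair.exon2.start,
        e2_end=pair.exon2.end,
        strand=pair.exon1.strand,
        gene_id=pair.gene_id,
    )


def build_junction_reference(
    pairs: list[BacksplicePair], genome: Fasta | str | Path
) -> list[JunctionEntry]:
    """Materialize scrambled-exome entries: exon2 sequence followed by exon1.

    The junction offset equals the exon2 segment length, so a read crossing
    position ``junction_offset`` spans the backsplice.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    entries = []
    for pair in pairs:
        seq1 = _exon_seq(pair.exon1, genome)
        seq2 = _exon_seq(pair.exon2, genome)
        entries.append(_entry_from_pair(pair, seq1, seq2))
    return entries


def build_control_reference(
    pairs: list[BacksplicePair],
    genome: Fasta | str | Path,
    mode: str,
    seed: int | None = None,
) -> list[JunctionEntry]:
    """Negative-control variant of the junction reference.

    ``randomized``: each distinct exon's sequence is shuffled once (composition
    preserved) with the given seed; every entry then uses the shuffled exon
    sequences in the same exon2+exon1 layout. ``flipped_exon2``: entries are
    exon1 followed by the reverse complement of exon2 (head-to-head junction),
    with junction_offset = exon1 length.
    """
    if mode not in CONTROL_MODES:
        raise ValueError(f"unknown control mode {mode!r}; expected one of {CONTROL_MODES}")
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))

    if mode == "flipped_exon2":
        entries = []
        for pair in pairs:
            seq1 = _exon_seq(pair.exon1, genome)
            seq2 = _exon_seq(pair.exon2, genome)
            entries.append(
                JunctionEntry(
                    junction_id=pair.junction_id,
                    sequence=seq1 + revcomp(seq2),
                    junction_offset=len(seq1),
                    exon1_len=len(seq1),
                    exon2_len=len(seq2),
                    chrom=pair.exon1.chrom,
                    e1_start=pair.exon1.start,
                    e1_end=pair.exon1.end,
                    e2_start=pair.exon2.start,
                    e2_end=pair.exon2.end,
                    strand=pair.exon1.strand,
                    gene_id=pair.gene_id,
                )
            )
        return entries

    # randomized: shuffle each distinct exon once, deterministically under seed
    rng = np.random.default_rng(0 if seed is None else seed)
    exon_keys = sorted({(p.exon1.gene_id, p.exon1.start, p.exon1.end) for p in pairs}
                       | {(p.exon2.gene_id, p.exon2.start, p.exon2.end) for p in pairs})
    exon_by_key: dict[tuple, Exon] = {}
    for p in pairs:
        exon_by_key.setdefault((p.exon1.gene_id, p.exon1.start, p.exon1.end), p.exon1)
        exon_by_key.setdefault((p.exon2.gene_id, p.exon2.start, p.exon2.end), p.exon2)
    shuffled: dict[tuple, str] = {}
    for key in exon_keys:
        seq = np.array(list(_exon_seq(exon_by_key[key], genome)))
        rng.shuffle(seq)
        shuffled[key] = "".join(seq)

    entries = []
    for pair in pairs:
        seq1 = shuffled[(pair.exon1.gene_id, pair.exon1.start, pair.exon1.end)]
        seq2 = shuffled[(pair.exon2.gene_id, pair.exon2.start, pair.exon2.end)]
        entries.append(_entry_from_pair(pair, seq1, seq2))
    return entries


def format_header(entry: JunctionEntry) -> str:
    return (
        f"{entry.junction_id}|{entry.chrom}|{entry.e1_start}-{entry.e1_end}|"
        f"{entry.e2_start}-{entry.e2_end}|{entry.strand}|offset={entry.junction_offset}"
    )


def parse_header(header: str) -> dict:
    """Inverse of :func:`format_header` (junction_id itself contains pipes)."""
    fields = header.split("|")
    gene_id, e1_rank, e2_rank, chrom, e1, e2, strand, off = fields
    e1_start, e1_end = (int(x) for x in e1.split("-"))
    e2_start, e2_end = (int(x) for x in e2.split("-"))
    return {
        "junction_id": f"{gene_id}|{e1_rank}|{e2_rank}",
        "gene_id": gene_id,
        "chrom": chrom,
        "e1_start": e1_start,
        "e1_end": e1_end,
        "e2_start": e2_start,
        "e2_end": e2_end,
        "strand": strand,
        "junction_offset": int(off.split("=")[1]),
    }


def write_reference(
    entries: list[JunctionEntry],
    fasta_path: str | Path,
    manifest_path: str | Path | None = None,
    mode: str = "real",
    seed: int | None = None,
    width: int = 70,
) -> None:
    """Write junction FASTA plus a TSV manifest (mode and seed in '#' comments)."""
    with open(fasta_path, "w") as fh:
        for e in entries:
            fh.write(f">{format_header(e)}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write(f"# circkit junction reference manifest; mode={mode}; seed={seed}\n")
            fh.write(
                "junction_id\tgene_id\tchrom\te1_start\te1_end\te2_start\te2_end\t"
                "strand\tjunction_offset\texon1_len\texon2_len\tlength\n"
            )
            for e in entries:
                fh.write(
                    f"{e.junction_id}\t{e.gene_id}\t{e.chrom}\t{e.e1_start}\t{e.e1_end}\t"
                    f"{e.e2_start}\t{e.e2_end}\t{e.strand}\t{e.junction_offset}\t"
                    f"{e.exon1_len}\t{e.exon2_len}\t{e.length}\n"
                )


def read_reference(fasta_path: str | Path) -> list[JunctionEntry]:
    """Load a junction reference FASTA written by :func:`write_reference`."""
    entries = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        meta = parse_header(header)
        seq = "".join(chunks)
        off = meta.pop("junction_offset")
        gene_id = meta.pop("gene_id")
        # segment lengths follow from offset and layout (exon2 first in the real
        # reference; the flipped control stores exon1 first — lengths still add up)
        entries.append(
            JunctionEntry(
                sequence=seq,
                junction_offset=off,
                exon1_len=len(seq) - off,
                exon2_len=off,
                gene_id=gene_id,
                **meta,
            )
        )

    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return entries


def build_reference_from_files(
    annotation_path: str | Path,
    genome_path: str | Path,
    max_exons_per_gene: int | None = None,
) -> tuple[list[GeneModel], list[BacksplicePair], list[JunctionEntry]]:
    """Convenience: annotation + genome -> (genes, pairs, entries)."""
    genes = load_annotation(annotation_path, genome_path)
    pairs: list[BacksplicePair] = []
    for gene in genes:
        if max_exons_per_gene is not None and gene.n_exons > max_exons_per_gene:
            logger.warning(
                "gene %s has %d exons > cap %d; skipped", gene.gene_id, gene.n_exons, max_exons_per_gene
            )
            continue
        pairs.extend(enumerate_backsplices(gene))
    entries = build_junction_reference(pairs, genome_path)
    return genes, pairs, entries
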