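"""Shared fixtures: a tiny hand-written genome and a generated fixture genome."""

from __future__ import annotations

import textwrap

import pytest
from pyfaidx import Fasta

from circkit import reference
from circkit.mapping import KmerIndex
from circkit.models import BacksplicePair, Exon, JunctionEntry
from circkit.simulate import make_fixture_genome

# Hand-written toy chromosome: coordinates below index into this string.
TOY_CHROM = (
    "ACGTACGTAC" * 4          # [0,40) padding
    + "AAAACCCCGGGGTTTTACGT"  # [40,60) geneA exon1
    + "TTTTTTTTTT"            # [60,70) intron
    + "CCGGCCGGCCGGCCGGCCGG"  # [70,90) geneA exon2
    + "ACGTACGTAC" * 2        # [90,110) spacer
    + "GATTACAGATTACAGATTAC"  # [110,130) geneB exon (minus strand, rank2)
    + "AAAAAAAAAA"            # [130,140) intron
    + "CTGACTGACTGACTGACTGA"  # [140,160) geneB exon (minus strand, rank1)
    + "ACGTACGTAC" * 2        # [160,180) tail
)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    path = d / "toy.fa"
    with open(path, "w") as fh:
        fh.write(">chrT\n")
        fh.write(textwrap.fill(TOY_CHROM, 60) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """geneA: + strand, 2 transcripts sharing exon1, one adding exon2.
    geneB: - strand, 2 exons (genomic order reversed in transcribed direction)."""
    d = tmp_path_factory.mktemp("toygtf")
    path = d / "toy.gtf"
    rows = [
        # GTF is 1-based inclusive
        ("chrT", "exon", 41, 60, "+", 'gene_id "geneA"; transcript_id "geneA.t1";'),
        ("chrT", "exon", 41, 60, "+", 'gene_id "geneA"; transcript_id "geneA.t2";'),
        ("chrT", "exon", 71, 90, "+", 'gene_id "geneA"; transcript_id "geneA.t2";'),
        ("chrT", "exon", 111, 130, "-", 'gene_id "geneB"; transcript_id "geneB.t1";'),
        ("chrT", "exon", 141, 160, "-", 'gene_id "geneB"; transcript_id "geneB.t1";'),
    ]
    with open(path, "w") as fh:
        for chrom, feat, start, end, strand, attrs in rows:
            fh.write(f"{chrom}\ttoy\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")
    return path


@pytest.fixture(scope="session")
def toy_fasta(toy_genome):
    return Fasta(str(toy_genome))


@pytest.fixture(scope="session")
def fixture_genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    return make_fixture_genome(d, n_genes=10, seed=42)


@pytest.fixture(scope="session")
def fixture_reference(fixture_genome):
    genes, pairs, entries = reference.build_reference_from_files(
        fixture_genome.gtf_path, fixture_genome.genome_path
    )
    return genes, pairs, entries


@pytest.fixture(scope="session")
def fixture_index(fixture_reference):
    _, _, entries = fixture_reference
    return KmerIndex(entries)


def make_entry(seq1: str, seq2: str, junction_id: str = "g|1|2") -> JunctionEntry:
    """Junction entry straight from exon sequences (exon2 first)."""
    return JunctionEntry(
        junction_id=junction_id,
        sequence=seq2 + seq1,
        junction_offset=len(seq2),
        exon1_len=len(seq1),
        exon2_len=len(seq2),
        chrom="chrT",
        e1_start=0,
        e1_end=len(seq1),
        e2_start=100,
        e2_end=100 + len(seq2),
        strand="+",
    )


def make_pair(gene_id="g", e1=(40, 60), e2=(70, 90), strand="+", chrom="chrT", r1=1, r2=2):
    exon1 = Exon(gene_id=gene_id, chrom=chrom, start=e1[0], end=e1[1], strand=strand, rank=r1)
    exon2 = Exon(gene_id=gene_id, chrom=chrom, start=e2[0], end=e2[1], strand=strand, rank=r2)
    return BacksplicePair(gene_id=gene_id, exon1=exon1, exon2=exon2)
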