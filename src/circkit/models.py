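"""Domain types for the circRNA detection pipeline.

Coordinates are 0-based half-open everywhere inside the package; GTF input is
converted on load and GTF/BED output converted on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, slots=True)
class Exon:
    """One collapsed exon of a gene.

    ``rank`` is 1-based in transcribed direction: on the minus strand rank 1 is
    the exon with the highest genomic coordinate.
    """

    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon {self.gene_id} has start >= end ({self.start}, {self.end})")
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class GeneModel:
    """Per-gene exon set, deduplicated across transcripts, in transcribed order."""

    gene_id: str
    exons: list[Exon]
    collapsed: bool = True

    def __post_init__(self) -> None:
        coords = [(e.start, e.end) for e in self.exons]
        if len(set(coords)) != len(coords):
            raise ValueError(f"gene {self.gene_id}: duplicate exon coordinates after collapsing")
        ranks = [e.rank for e in self.exons]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError(f"gene {self.gene_id}: exon ranks not strictly increasing")
        if len({(e.chrom, e.strand) for e in self.exons}) > 1:
            raise ValueError(f"gene {self.gene_id}: exons span multiple chrom/strand")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True, slots=True)
class BacksplicePair:
    """An (upstream exon1, downstream exon2) pair joined head-to-tail.

    exon1.rank <= exon2.rank; equality is the single-exon backsplice where the
    3' end of an exon is joined back to its own 5' start.
    """

    gene_id: str
    exon1: Exon
    exon2: Exon

    def __post_init__(self) -> None:
        if self.exon1.rank > self.exon2.rank:
            raise ValueError("exon1 must be upstream of (or equal to) exon2 in transcribed order")
        if self.exon1.gene_id != self.gene_id or self.exon2.gene_id != self.gene_id:
            raise ValueError("both exons must belong to the pair's gene")

    @property
    def junction_id(self) -> str:
        return f"{self.gene_id}|{self.exon1.rank}|{self.exon2.rank}"


@dataclass(slots=True)
class JunctionEntry:
    """One scrambled-exome reference entry: exon2 sequence followed by exon1.

    ``junction_offset`` is the 0-based position where the second segment begins,
    i.e. the backsplice point. For the real reference the first segment is
    exon2 (offset == exon2_len); the flipped-Exon2 control places exon1 first.
    """

    junction_id: str
    sequence: str
    junction_offset: int
    exon1_len: int
    exon2_len: int
    chrom: str = ""
    e1_start: int = 0
    e1_end: int = 0
    e2_start: int = 0
    e2_end: int = 0
    strand: str = "+"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.exon1_len + self.exon2_len:
            raise ValueError(f"{self.junction_id}: sequence length != exon1_len + exon2_len")
        if not 0 < self.junction_offset < len(self.sequence):
            raise ValueError(f"{self.junction_id}: junction_offset outside sequence")
        if not self.gene_id:
            self.gene_id = self.junction_id.split("|")[0]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class ReadPairAlignment:
    """A paired-end fragment placed on one reference entry (junction or chromosome)."""

    fragment_id: str
    entry_id: str
    m1_start: int
    m1_end: int
    m2_start: int
    m2_end: int
    m1_strand: str
    m2_strand: str
    primary: bool = True
    n_mismatch: int = 0
    sample_id: str = "sample1"

    def __post_init__(self) -> None:
        if self.m1_start >= self.m1_end or self.m2_start >= self.m2_end:
            raise ValueError(f"{self.fragment_id}: mate start >= end")

    @property
    def outer_start(self) -> int:
        return min(self.m1_start, self.m2_start)

    @property
    def outer_end(self) -> int:
        return max(self.m1_end, self.m2_end)

    @property
    def span(self) -> int:
        return self.outer_end - self.outer_start


@dataclass(slots=True)
class EvidenceClass:
    """Classification of one fragment against one junction entry."""

    fragment_id: str
    junction_id: str
    evidence: str  # junctional | supportive | none
    overlap_left: int = 0
    overlap_right: int = 0
    sample_id: str = "sample1"


@dataclass(slots=True)
class CandidateCircRNA:
    """A called backsplice junction with per-sample evidence counts."""

    junction_id: str
    gene_id: str
    chrom: str
    e1_start: int
    e2_end: int
    strand: str
    junctional_count: dict[str, int] = field(default_factory=dict)
    supported_count: dict[str, int] = field(default_factory=dict)
    passed_samples: list[str] = field(default_factory=list)
    passed: bool = False

    def total_junctional(self) -> int:
        return sum(self.junctional_count.values())

    def total_supported(self) -> int:
        return sum(self.supported_count.values())


@dataclass(slots=True)
class SimulationTruth:
    """Planted circles and depths for one simulation scenario."""

    true_circles: set[str]
    circle_depth: dict[str, int]
    linear_depth: dict[str, int]
    seed: int


@dataclass(slots=True)
class EvalResult:
    """Confusion counts and derived rates for one evaluation."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


@dataclass(frozen=True, slots=True)
class SeedMatch:
    """One miRNA seed-complementary site on a target sequence."""

    mirna_id: str
    target_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1
    position: int  # 0-based start on the target
    matched: str
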