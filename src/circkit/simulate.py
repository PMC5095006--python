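"""Synthetic genomes, circular/linear read mixtures and caller benchmarking.

The simulator emulates the benchmark design used to characterize the caller: a
set of backsplice junctions is selected at random from the reference, paired-end
fragments are drawn from each circularized sequence (positions wrap around the
circle, so junction-spanning and interior fragments both occur at their natural
frequencies) on top of a background of fragments from the canonical linear
transcripts, and the called set is scored against the planted truth as
sensitivity TP/(TP+FN) and precision TP/(TP+FP).

Defaults describe a desk-scale short-insert experiment: 50 bp mates, fragment
lengths Normal(85, 8) truncated at the read length (mates overlap, as in
short-insert libraries), i.i.d. substitution errors, exons of 70-120 bp. The
circle model is the two-exon junction sequence treated as circular, so insert
sizes are chosen commensurate with that circle scale: a fragment longer than
the shorter exon cannot anchor a junctional mate on both sides, and a fragment
crossing the canonical-splice point of the circle is indistinguishable from a
linear fragment and carries no backsplice evidence. Depth is defined as
fragments per circle (the expression level of the planted circle), not
per-base coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from circkit.models import EvalResult, GeneModel, JunctionEntry, SimulationTruth
from circkit.sequtils import revcomp

BASES = np.array(list("ACGT"))

DEFAULT_READ_LEN = 50
DEFAULT_FRAG_MEAN = 85.0
DEFAULT_FRAG_SD = 8.0


@dataclass(slots=True)
class FixtureGenome:
    """Paths and truth manifest for a generated toy genome + annotation."""

    genome_path: Path
    gtf_path: Path
    manifest: list[dict]  # one dict per gene: gene_id, chrom, strand, exons [(start, end), ...]
    seed: int

    @property
    def n_genes(self) -> int:
        return len(self.manifest)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_fixture_genome(
    out_dir: str | Path,
    n_genes: int = 50,
    exons_per_gene: tuple[int, int] = (3, 8),
    exon_len: tuple[int, int] = (70, 120),
    intron_len: tuple[int, int] = (60, 200),
    intergenic_len: tuple[int, int] = (100, 300),
    seed: int = 0,
    chrom_name: str = "chrS",
) -> FixtureGenome:
    """Write a seed-deterministic toy genome FASTA + GTF with known structure.

    Genes are laid out non-overlapping along one synthetic chromosome with
    random strands; the returned manifest is the ground truth for annotation
    tests (exon coordinates are 0-based half-open).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chunks: list[str] = []
    pos = 0
    manifest: list[dict] = []
    for g in range(n_genes):
        gap = int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))
        chunks.append(_random_seq(rng, gap))
        pos += gap
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for i in range(n_ex):
            if i > 0:
                ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
                chunks.append(_random_seq(rng, ilen))
                pos += ilen
            elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
            chunks.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        manifest.append(
            {"gene_id": f"gene{g + 1:03d}", "chrom": chrom_name, "strand": strand, "exons": exons}
        )
    chunks.append(_random_seq(rng, int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))))
    genome_seq = "".join(chunks)

    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{chrom_name}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i : i + 70] + "\n")

    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for gene in manifest:
            gid = gene["gene_id"]
            g_start = gene["exons"][0][0] + 1
            g_end = gene["exons"][-1][1]
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            fh.write(
                f"{chrom_name}\tcirckit_sim\tgene\t{g_start}\t{g_end}\t.\t{gene['strand']}\t.\t"
                f'gene_id "{gid}";\n'
            )
            for s, e in gene["exons"]:
                fh.write(
                    f"{chrom_name}\tcirckit_sim\texon\t{s + 1}\t{e}\t.\t{gene['strand']}\t.\t{attrs}\n"
                )

    faidx = genome_path.with_suffix(".fa.fai")
    if faidx.exists():  # stale index from a previous run would shadow the new sequence
        faidx.unlink()
    return FixtureGenome(genome_path=genome_path, gtf_path=gtf_path, manifest=manifest, seed=seed)


def plant_circles(
    entries: Sequence[JunctionEntry],
    n_circles: int = 200,
    depth: int = 20,
    linear_depth: int = 30,
    seed: int = 0,
) -> SimulationTruth:
    """Select ``n_circles`` junctions uniformly without replacement as true circles."""
    ids = sorted(e.junction_id for e in entries)
    if n_circles > len(ids):
        raise ValueError(f"cannot plant {n_circles} circles in a reference of {len(ids)} junctions")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(ids), size=n_circles, replace=False))
    true_ids = [ids[i] for i in chosen]
    genes = sorted({jid.split("|")[0] for jid in ids})
    return SimulationTruth(
        true_circles=set(true_ids),
        circle_depth={jid: depth for jid in true_ids},
        linear_depth={g: linear_depth for g in genes},
        seed=seed,
    )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _fragment_reads(
    frag: str, read_len: int, rng: np.random.Generator, error_rate: float
) -> tuple[str, str]:
    """Mate sequences of a fragment; read1 is the forward or reverse mate at random."""
    fwd = frag[:read_len]
    rev = revcomp(frag[-read_len:])
    r1, r2 = (fwd, rev) if rng.random() < 0.5 else (rev, fwd)
    return _apply_errors(r1, rng, error_rate), _apply_errors(r2, rng, error_rate)


def _draw_frag_len(rng: np.random.Generator, mean: float, sd: float, read_len: int) -> int:
    return max(read_len, int(round(rng.normal(mean, sd))))


def linear_transcript(gene: GeneModel, genome) -> str:
    """Spliced canonical transcript: exon sequences in transcribed order."""
    from circkit.reference import _exon_seq

    return "".join(_exon_seq(e, genome) for e in gene.exons)


def simulate_reads(
    truth: SimulationTruth,
    entries: Sequence[JunctionEntry],
    genes: Sequence[GeneModel],
    genome,
    read_len: int = DEFAULT_READ_LEN,
    frag_mean: float = DEFAULT_FRAG_MEAN,
    frag_sd: float = DEFAULT_FRAG_SD,
    error_rate: float = 0.01,
    seed: int | None = None,
) -> list[tuple[str, str, str]]:
    """Draw paired-end fragments from planted circles plus linear background.

    Circle fragments start uniformly on the circularized junction sequence and
    wrap modulo its length; linear fragments are drawn from the spliced
    transcript (lengths clamped to the transcript when necessary). Returns
    (fragment_id, read1, read2) tuples; ids encode the source for truth checks.
    """
    from pyfaidx import Fasta

    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    by_id = {e.junction_id: e for e in entries}
    reads: list[tuple[str, str, str]] = []

    for jid in sorted(truth.true_circles):
        entry = by_id[jid]
        circ = entry.sequence
        L = len(circ)
        for i in range(truth.circle_depth[jid]):
            flen = _draw_frag_len(rng, frag_mean, frag_sd, read_len)
            start = int(rng.integers(0, L))
            tiled = circ * (flen // L + 2)
            frag = tiled[start : start + flen]
            r1, r2 = _fragment_reads(frag, read_len, rng, error_rate)
            reads.append((f"circ:{jid}:{i}", r1, r2))

    gene_by_id = {g.gene_id: g for g in genes}
    for gene_id in sorted(truth.linear_depth):
        depth = truth.linear_depth[gene_id]
        if depth <= 0 or gene_id not in gene_by_id:
            continue
        tx = linear_transcript(gene_by_id[gene_id], genome)
        T = len(tx)
        for i in range(depth):
            flen = min(_draw_frag_len(rng, frag_mean, frag_sd, read_len), T)
            start = int(rng.integers(0, T - flen + 1))
            frag = tx[start : start + flen]
            r1, r2 = _fragment_reads(frag, read_len, rng, error_rate)
            reads.append((f"lin:{gene_id}:{i}", r1, r2))
    return reads


def write_fastq(reads: Iterable[tuple[str, str, str]], fastq1: str | Path, fastq2: str | Path) -> None:
    """Standard 4-line FASTQ records with /1 and /2 mate suffixes."""
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for name, r1, r2 in reads:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def evaluate_calls(called: set[str] | Sequence, truth: SimulationTruth) -> EvalResult:
    """Score a called junction set against the planted truth by set algebra."""
    if not isinstance(called, set):
        called = {c.junction_id if hasattr(c, "junction_id") else c for c in called}
    tp = len(called & truth.true_circles)
    fp = len(called - truth.true_circles)
    fn = len(truth.true_circles - called)
    return EvalResult(tp=tp, fp=fp, fn=fn)


def run_detection(
    reads: Sequence[tuple[str, str, str]],
    entries: Sequence[JunctionEntry],
    sample_id: str = "sim",
    min_overlap: int = 10,
    min_junctional: int = 3,
    min_supported: int = 10,
    policy: str = "A",
    k: int = 15,
    max_mismatch: int = 2,
    index=None,
):
    """Map -> dedup -> classify -> call; returns (candidates, passed junction_ids)."""
    from circkit.calling import call_candidates, classify_alignments, passed_junctions
    from circkit.mapping import KmerIndex, map_pairs, remove_duplicates

    if index is None:
        index = KmerIndex(entries, k=k)
    alignments = map_pairs(reads, index, sample_id=sample_id, max_mismatch=max_mismatch)
    deduped = remove_duplicates(alignments)
    evidence = classify_alignments(deduped, index.entries, min_overlap)
    candidates = call_candidates(evidence, index.entries, min_junctional, min_supported, policy)
    return candidates, passed_junctions(candidates)


@dataclass(slots=True)
class DepthSweepRow:
    depth: int
    seed: int
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float | None


def depth_sweep(
    entries: Sequence[JunctionEntry],
    genes: Sequence[GeneModel],
    genome,
    depths: Sequence[int] = (2, 5, 10, 20),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_circles: int = 200,
    linear_depth: int = 30,
    error_rate: float = 0.01,
    index=None,
    **detect_kwargs,
) -> list[DepthSweepRow]:
    """Sensitivity/precision of the full pipeline across planted depths and seeds."""
    from circkit.mapping import KmerIndex

    if index is None:
        index = KmerIndex(entries)
    rows = []
    for seed in seeds:
        for depth in depths:
            truth = plant_circles(entries, n_circles=n_circles, depth=depth,
                                  linear_depth=linear_depth, seed=seed)
            reads = simulate_reads(truth, entries, genes, genome, error_rate=error_rate)
            _, called = run_detection(reads, entries, index=index, **detect_kwargs)
            res = evaluate_calls(called, truth)
            rows.append(
                DepthSweepRow(
                    depth=depth,
                    seed=seed,
                    tp=res.tp,
                    fp=res.fp,
                    fn=res.fn,
                    sensitivity=res.sensitivity if res.sensitivity is not None else float("nan"),
                    precision=res.precision,
                )
            )
    return rows


def simulate_rnase_r_counts(
    n_circ: int = 60,
    n_mrna: int = 60,
    depletion: float = 10.0,
    mean_count: float = 200.0,
    length_range: tuple[int, int] = (200, 2000),
    seed: int = 0,
):
    """Counts for an exoribonuclease-digestion experiment analog.

    Untreated counts are Poisson around ``mean_count`` for every feature; in
    the treated library linear (mRNA) features are depleted ``depletion``-fold
    while circles are spared. Returns (treated, untreated, lengths,
    feature_class) series keyed by feature id.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ids = [f"circ{i:03d}" for i in range(n_circ)] + [f"gene{i:03d}" for i in range(n_mrna)]
    classes = pd.Series(["circ"] * n_circ + ["mRNA"] * n_mrna, index=ids, name="feature_class")
    base = rng.gamma(shape=4.0, scale=mean_count / 4.0, size=len(ids))
    untreated = pd.Series(rng.poisson(base), index=ids, dtype=int)
    treated_lam = np.where(classes == "circ", base, base / depletion)
    treated = pd.Series(rng.poisson(treated_lam), index=ids, dtype=int)
    lengths = pd.Series(rng.integers(length_range[0], length_range[1] + 1, size=len(ids)),
                        index=ids, dtype=int)
    return treated, untreated, lengths, classes
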