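"""miRNA seed-match scanning and sponge (ceRNA) scoring.

A transcript can act as a miRNA sponge when it carries multiple sites
complementary to a miRNA's seed (miRNA bases 2-7). Sites are classified with
the canonical hierarchy, scanning the target 5'->3':

* ``8mer``    — reverse complement of miRNA bases 2-8, followed by A
* ``7mer-m8`` — reverse complement of miRNA bases 2-8
* ``7mer-A1`` — reverse complement of miRNA bases 2-7, followed by A

(the trailing A on the target sits opposite miRNA position 1). Each target
position is reported once with the strongest matching type; overlapping sites
at different positions are all reported. circRNA targets are covalently
closed, so scanning can wrap across the backsplice point to catch
junction-straddling sites.

Sponge strength of differentially expressed circRNAs toward a miRNA-x is
summarized as the weighted expression

    E_circ(x) = (1/N) * sum_i n_xi * x_i

over the N circRNAs carrying sites for miRNA-x, where n_xi is the seed-match
count on circRNA i and x_i its (log2) fold-change expression. For a downstream
gene targeted by a set of miRNAs, Average E_circ is the arithmetic mean of the
E_circ values of its targeting miRNAs. miRNA->gene target edges are consumed
from a user-supplied table, not predicted here.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from circkit.models import SeedMatch
from circkit.sequtils import normalize, revcomp

logger = logging.getLogger(__name__)

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1")


def _site_patterns(mirna_seq: str) -> list[tuple[str, str]]:
    """(site_type, target-side pattern 5'->3') in strength order."""
    m = normalize(mirna_seq)
    if len(m) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt, got {len(m)}")
    seed27 = m[1:7]
    seed28 = m[1:8]
    return [
        ("8mer", revcomp(seed28) + "A"),
        ("7mer-m8", revcomp(seed28)),
        ("7mer-A1", revcomp(seed27) + "A"),
    ]


def find_seed_matches(
    target_seq: str,
    mirna_seq: str,
    mirna_id: str = "miRNA",
    target_id: str = "target",
    circular: bool = False,
) -> list[SeedMatch]:
    """All seed-complementary sites of one miRNA on one target.

    Windows containing ambiguous bases are skipped. With ``circular=True`` the
    scan wraps across the end/start seam (positions stay < target length), for
    covalently closed targets whose junction can itself harbor a site.
    """
    target = normalize(target_seq)
    L = len(target)
    patterns = _site_patterns(mirna_seq)
    max_len = max(len(p) for _, p in patterns)
    scan = target + (target[: max_len - 1] if circular and L >= max_len else "")

    matches: list[SeedMatch] = []
    n_positions = L if circular and L >= max_len else max(0, len(scan) - min(len(p) for _, p in patterns) + 1)
    for pos in range(n_positions):
        for site_type, pattern in patterns:
            window = scan[pos : pos + len(pattern)]
            if len(window) < len(pattern):
                continue
            if "N" in window:
                continue
            if window == pattern:
                matches.append(
                    SeedMatch(
                        mirna_id=mirna_id,
                        target_id=target_id,
                        site_type=site_type,
                        position=pos,
                        matched=window,
                    )
                )
                break  # strongest type only at this position
    return matches


def scan_targets(
    targets: Mapping[str, str],
    mirnas: Mapping[str, str],
    circular_targets: set[str] | None = None,
) -> list[SeedMatch]:
    """Scan every target against every miRNA."""
    circular_targets = circular_targets or set()
    out: list[SeedMatch] = []
    for tid in sorted(targets):
        for mid in sorted(mirnas):
            out.extend(
                find_seed_matches(
                    targets[tid],
                    mirnas[mid],
                    mirna_id=mid,
                    target_id=tid,
                    circular=tid in circular_targets,
                )
            )
    return out


def seed_density(
    targets: Mapping[str, str],
    mirnas: Mapping[str, str],
    target_class: Mapping[str, str] | None = None,
    circular_targets: set[str] | None = None,
) -> pd.DataFrame:
    """Per-target seed matches per kilobase, with optional class labels.

    The returned frame (one row per target: n_matches, length, density,
    target_class) feeds class-level comparisons such as circRNA vs 3'UTR/5'UTR/
    CDS density distributions and their empirical CDFs.
    """
    matches = scan_targets(targets, mirnas, circular_targets)
    counts: dict[str, int] = {tid: 0 for tid in targets}
    for m in matches:
        counts[m.target_id] += 1
    rows = []
    for tid in sorted(targets):
        length = len(targets[tid])
        if length <= 0:
            raise ValueError(f"target {tid} has zero length")
        rows.append(
            {
                "target_id": tid,
                "n_matches": counts[tid],
                "length": length,
                "density_per_kb": counts[tid] * 1000.0 / length,
                "target_class": (target_class or {}).get(tid, "unknown"),
            }
        )
    return pd.DataFrame(rows).set_index("target_id")


def ecdf_table(densities: pd.Series) -> pd.DataFrame:
    """Empirical CDF of a density distribution (sorted value, cumulative fraction)."""
    x = densities.sort_values().to_numpy()
    n = len(x)
    return pd.DataFrame({"density_per_kb": x, "ecdf": [(i + 1) / n for i in range(n)]})


def e_circ(circ_set: Sequence[tuple[float, float]]) -> float:
    """Weighted expression of circRNAs targeting one miRNA.

    ``circ_set`` holds (n_xi, x_i) per circRNA: seed-match count and
    fold-change expression. Returns (sum n_xi * x_i) / N.
    """
    if not circ_set:
        raise ValueError("E_circ undefined for zero targeting circRNAs")
    return sum(n * x for n, x in circ_set) / len(circ_set)


def e_circ_by_mirna(network: pd.DataFrame) -> pd.Series:
    """E_circ per miRNA from a circRNA->miRNA edge table.

    ``network`` columns: circ_id, mirna_id, n_sites, log2fc. Edges with zero
    sites contribute nothing and are dropped before counting N.
    """
    edges = network[network["n_sites"] > 0]
    out = {}
    for mid, grp in edges.groupby("mirna_id"):
        out[mid] = e_circ(list(zip(grp["n_sites"], grp["log2fc"])))
    return pd.Series(out, name="E_circ").sort_index()


def average_e_circ(
    gene_mirna_edges: pd.DataFrame,
    e_circ_values: pd.Series | Mapping[str, float],
) -> pd.Series:
    """Average E_circ per downstream target gene.

    ``gene_mirna_edges`` columns: mirna_id, gene_id (the externally supplied
    target predictions). For each gene, the mean of E_circ over its targeting
    miRNAs with a defined value; genes with none are dropped with a log note.
    """
    e = pd.Series(e_circ_values)
    out = {}
    n_dropped = 0
    for gid, grp in gene_mirna_edges.groupby("gene_id"):
        vals = [e[mid] for mid in grp["mirna_id"].unique() if mid in e and not math.isnan(e[mid])]
        if not vals:
            n_dropped += 1
            continue
        out[gid] = sum(vals) / len(vals)
    if n_dropped:
        logger.info("dropped %d genes with no defined E_circ among targeting miRNAs", n_dropped)
    return pd.Series(out, name="average_E_circ").sort_index()


def read_fasta_dict(path) -> dict[str, str]:
    """id -> sequence for a (mature miRNA or target) FASTA file."""
    import pysam

    out = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out[rec.name] = rec.sequence
    return out


def write_matches(matches: Iterable[SeedMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttarget_id\tsite_type\tposition\tmatched\n")
        for m in matches:
            fh.write(f"{m.mirna_id}\t{m.target_id}\t{m.site_type}\t{m.position}\t{m.matched}\n")
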