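"""Expression summarization for circular and linear isoforms.

circRNA expression per junction is the aggregate count of distinct fragments
supporting the backsplice (junctional + supportive). Linear expression for the
same exon pair counts concordant genome fragments touching either exon — a
deliberately conservative rule, since exon-internal reads cannot be assigned to
the circular or linear form and are all credited to the linear one. The
circular:linear ratio of those counts estimates how a backsplice-capable exon
pair is used.

Also here: FPKM, RNase-R-style treated/untreated fold-change enrichment with a
one-sided rank comparison of circRNA vs mRNA distributions, the low-expression
prefilter (>= 3 counts in >= 3 samples), and the z-scored log2-CPM transform
used for expression heatmaps.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from circkit.models import BacksplicePair, EvidenceClass, ReadPairAlignment

CIRC_ONLY = float("inf")  # sentinel ratio for circ > 0, linear == 0


def circ_counts(
    evidence: Iterable[EvidenceClass],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Junction x sample matrix of backsplice-supporting fragment counts.

    Each cell is the number of distinct fragments classified junctional or
    supportive for that junction in that sample.
    """
    tally: dict[tuple[str, str], set[str]] = {}
    for ev in evidence:
        if ev.evidence in ("junctional", "supportive"):
            tally.setdefault((ev.junction_id, ev.sample_id), set()).add(ev.fragment_id)
    rows = sorted({jid for jid, _ in tally})
    cols = sorted({s for _, s in tally} | set(samples or []))
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (jid, s), frags in tally.items():
        mat.loc[jid, s] = len(frags)
    mat.index.name = "junction_id"
    return mat


def linear_counts(
    genome_alignments: Iterable[ReadPairAlignment],
    pairs: Sequence[BacksplicePair],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Junction x sample matrix of linear-evidence fragment counts.

    A genome fragment counts toward a junction when either mate overlaps either
    exon of the pair by >= 1 base in concordant FR orientation (leftmost mate
    forward, rightmost reverse). Divergent pairs — circular evidence by
    definition — are excluded, and each fragment counts once per junction.
    """
    trees: dict[str, IntervalTree] = {}
    for i, pair in enumerate(pairs):
        for exon in (pair.exon1, pair.exon2):
            trees.setdefault(exon.chrom, IntervalTree()).addi(exon.start, exon.end, i)

    counts: dict[tuple[str, str], set[str]] = {}
    sample_set = set(samples or [])
    for aln in genome_alignments:
        sample_set.add(aln.sample_id)
        if aln.m1_start <= aln.m2_start:
            left_strand, right_strand = aln.m1_strand, aln.m2_strand
        else:
            left_strand, right_strand = aln.m2_strand, aln.m1_strand
        if not (left_strand == "+" and right_strand == "-"):
            continue  # discordant/divergent: not linear evidence
        tree = trees.get(aln.entry_id)
        if tree is None:
            continue
        hit: set[int] = set()
        for s, e in ((aln.m1_start, aln.m1_end), (aln.m2_start, aln.m2_end)):
            for iv in tree.overlap(s, e):
                hit.add(iv.data)
        for i in hit:
            counts.setdefault((pairs[i].junction_id, aln.sample_id), set()).add(aln.fragment_id)

    rows = sorted(p.junction_id for p in pairs)
    cols = sorted(sample_set)
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (jid, s), frags in counts.items():
        mat.loc[jid, s] = len(frags)
    mat.index.name = "junction_id"
    return mat


def circ_linear_ratio(circ: pd.DataFrame | pd.Series, linear: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Per-junction circular:linear abundance ratio.

    Matrix inputs are summed across samples first. Junctions with zero counts
    in both forms are dropped; circ > 0 with linear == 0 yields the inf
    sentinel, labelled ``circ_only``.
    """
    c = circ.sum(axis=1) if isinstance(circ, pd.DataFrame) else circ
    l = linear.sum(axis=1) if isinstance(linear, pd.DataFrame) else linear
    idx = c.index.union(l.index)
    c = c.reindex(idx, fill_value=0)
    l = l.reindex(idx, fill_value=0)
    keep = (c + l) > 0
    c, l = c[keep], l[keep]
    with np.errstate(divide="ignore"):
        ratio = np.where(l > 0, c / np.where(l > 0, l, 1), CIRC_ONLY)
    out = pd.DataFrame(
        {
            "circ_count": c.astype(int),
            "linear_count": l.astype(int),
            "ratio": ratio,
            "label": np.where(l > 0, "ratio", "circ_only"),
        }
    )
    out.index.name = "junction_id"
    return out


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, float],
    mapped_totals: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments."""
    lengths = pd.Series(lengths).reindex(counts.index)
    totals = pd.Series(mapped_totals).reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("feature lengths must be positive for all rows")
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("mapped totals must be positive for all samples")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def enrichment_fold_change(
    treated_counts: pd.Series,
    untreated_counts: pd.Series,
    lengths: pd.Series,
    treated_total: float,
    untreated_total: float,
    feature_class: pd.Series,
    pseudocount: float = 1.0,
    genes_with_circ: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Treated/untreated FPKM fold change per feature, compared across classes.

    The pseudocount is added in fragment units before the FPKM transform, so it
    is negligible at high counts. ``feature_class`` labels each feature
    ``circ`` or ``mRNA``; when ``genes_with_circ`` is given, mRNA features are
    restricted to that universe (genes producing at least one detectable
    circular isoform). Returns the per-feature table and a one-sided
    Mann-Whitney comparison (circ fold changes greater than mRNA's).
    """
    idx = treated_counts.index.intersection(untreated_counts.index)
    if len(idx) == 0:
        raise ValueError("no overlapping features between treated and untreated")
    feature_class = feature_class.reindex(idx)
    if genes_with_circ is not None:
        keep = (feature_class != "mRNA") | feature_class.index.isin(genes_with_circ)
        idx = idx[keep.reindex(idx).to_numpy()]
        feature_class = feature_class.reindex(idx)

    def _fpkm(c: pd.Series, total: float) -> pd.Series:
        m = fpkm(
            pd.DataFrame({"s": c.reindex(idx) + pseudocount}),
            lengths.reindex(idx),
            {"s": total},
        )
        return m["s"]

    fc = _fpkm(treated_counts, treated_total) / _fpkm(untreated_counts, untreated_total)
    table = pd.DataFrame({"feature_class": feature_class, "fold_change": fc})
    table.index.name = "feature_id"

    circ_fc = table.loc[table.feature_class == "circ", "fold_change"]
    mrna_fc = table.loc[table.feature_class == "mRNA", "fold_change"]
    if len(circ_fc) and len(mrna_fc):
        stat, pval = stats.mannwhitneyu(circ_fc, mrna_fc, alternative="greater")
    else:
        stat, pval = float("nan"), float("nan")
    report = {
        "median_circ_fc": float(circ_fc.median()) if len(circ_fc) else float("nan"),
        "median_mrna_fc": float(mrna_fc.median()) if len(mrna_fc) else float("nan"),
        "mannwhitney_U": float(stat),
        "p_value": float(pval),
        "n_circ": int(len(circ_fc)),
        "n_mrna": int(len(mrna_fc)),
    }
    return table, report


def prefilter_counts(matrix: pd.DataFrame, min_count: int = 3, min_samples: int = 3) -> pd.DataFrame:
    """Keep rows expressed at >= min_count in >= min_samples samples."""
    if matrix.shape[1] < min_samples:
        raise ValueError(
            f"matrix has {matrix.shape[1]} samples; prefilter requires >= {min_samples}"
        )
    keep = (matrix >= min_count).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def zscore_log2cpm(matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-row z-score of log2 counts-per-million. Constant rows map to 0."""
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive column total")
    cpm = matrix.div(totals, axis=1) * 1e6
    log = np.log2(cpm + pseudocount)
    mu = log.mean(axis=1)
    sd = log.std(axis=1, ddof=0)
    z = log.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)
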