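"""Count matrices, ratios, FPKM, enrichment, prefilter, z-scored log2-CPM."""

import numpy as np
import pandas as pd
import pytest

from circkit import quantify
from circkit.models import EvidenceClass, ReadPairAlignment
from circkit.simulate import simulate_rnase_r_counts
from tests.conftest import make_pair


def _ev(frag, jid, kind, sample="s1"):
    return EvidenceClass(frag, jid, kind, 0, 0, sample)


class TestCircCounts:
    def test_junctional_plus_supportive(self):
        ev = [_ev(f"j{i}", "a|1|2", "junctional") for i in range(3)]
        ev += [_ev(f"s{i}", "a|1|2", "supportive") for i in range(2)]
        mat = quantify.circ_counts(ev)
        assert mat.loc["a|1|2", "s1"] == 5

    def test_absent_junction_sample_is_zero(self):
        ev = [_ev("j0", "a|1|2", "junctional", "s1")]
        mat = quantify.circ_counts(ev, samples=["s1", "s2"])
        assert mat.loc["a|1|2", "s2"] == 0

    def test_column_sums_equal_classified_fragments(self):
        rng = np.random.default_rng(0)
        ev = []
        per_sample = {"s1": 0, "s2": 0}
        for i in range(200):
            sample = "s1" if rng.random() < 0.5 else "s2"
            kind = ["junctional", "supportive", "none"][rng.integers(0, 3)]
            jid = f"g{rng.integers(0, 5)}|1|2"
            ev.append(_ev(f"f{i}", jid, kind, sample))
            if kind != "none":
                per_sample[sample] += 1
        mat = quantify.circ_counts(ev)
        for s, total in per_sample.items():
            assert mat[s].sum() == total


class TestLinearCounts:
    def _frag(self, frag, chrom, m1, m2, strands=("+", "-"), sample="s1"):
        return ReadPairAlignment(
            fragment_id=frag, entry_id=chrom, m1_start=m1[0], m1_end=m1[1],
            m2_start=m2[0], m2_end=m2[1], m1_strand=strands[0], m2_strand=strands[1],
            sample_id=sample,
        )

    def test_overlapping_fragments_counted(self):
        pair = make_pair(e1=(40, 60), e2=(70, 90))
        frags = [self._frag(f"in{i}", "chrT", (45, 55), (70, 80)) for i in range(7)]
        frags += [self._frag(f"out{i}", "chrT", (200, 230), (250, 280)) for i in range(3)]
        mat = quantify.linear_counts(frags, [pair])
        assert mat.loc[pair.junction_id, "s1"] == 7

    def test_divergent_pairs_excluded(self):
        pair = make_pair()
        good = self._frag("a", "chrT", (45, 55), (70, 80))
        divergent = self._frag("b", "chrT", (45, 55), (70, 80), strands=("-", "+"))
        mat = quantify.linear_counts([good, divergent], [pair])
        assert mat.loc[pair.junction_id, "s1"] == 1

    def test_matches_brute_force_interval_oracle(self):
        rng = np.random.default_rng(1)
        pairs = [make_pair(gene_id=f"g{i}", e1=(i * 300, i * 300 + 80), e2=(i * 300 + 120, i * 300 + 200))
                 for i in range(4)]
        frags = []
        for i in range(150):
            s = int(rng.integers(0, 1300))
            frags.append(self._frag(f"f{i}", "chrT", (s, s + 40), (s + 60, s + 100)))
        mat = quantify.linear_counts(frags, pairs)

        def overlaps(a, b, c, d):
            return a < d and c < b

        for pair in pairs:
            expect = 0
            for fr in frags:
                hit = False
                for (s, e) in ((fr.m1_start, fr.m1_end), (fr.m2_start, fr.m2_end)):
                    for ex in (pair.exon1, pair.exon2):
                        if overlaps(s, e, ex.start, ex.end):
                            hit = True
                expect += hit
            assert mat.loc[pair.junction_id, "s1"] == expect


class TestCircLinearRatio:
    def test_basic_ratio_and_sentinels(self):
        circ = pd.Series({"a": 5, "b": 10, "c": 0})
        linear = pd.Series({"a": 50, "b": 0, "c": 0})
        out = quantify.circ_linear_ratio(circ, linear)
        assert out.loc["a", "ratio"] == pytest.approx(0.1)
        assert np.isinf(out.loc["b", "ratio"])
        assert out.loc["b", "label"] == "circ_only"
        assert "c" not in out.index  # both zero -> dropped

    def test_planted_high_ratio_fraction_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        ids = [f"j{i}" for i in range(n)]
        high = set(rng.choice(n, size=20, replace=False))  # 10% planted with ratio > 1
        circ = pd.Series([30 if i in high else 2 for i in range(n)], index=ids)
        linear = pd.Series([10 if i in high else 40 for i in range(n)], index=ids)
        out = quantify.circ_linear_ratio(circ, linear)
        assert (out["ratio"] > 1).sum() == 20


class TestFpkm:
    def test_unit_case(self):
        mat = pd.DataFrame({"s": [10]}, index=["f"])
        out = quantify.fpkm(mat, pd.Series({"f": 1000}), {"s": 1_000_000})
        assert out.loc["f", "s"] == pytest.approx(10.0)

    def test_linearity_and_scaling_invariance(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.integers(0, 500, size=(10, 4)),
                           index=[f"f{i}" for i in range(10)], columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 3000, size=10), index=mat.index)
        totals = pd.Series(rng.integers(10_000, 50_000, size=4), index=mat.columns)
        base = quantify.fpkm(mat, lengths, totals)
        assert np.allclose(quantify.fpkm(mat * 2, lengths, totals), base * 2)
        assert np.allclose(quantify.fpkm(mat * 3, lengths, totals * 3), base)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.integers(0, 100, size=(5, 3)),
                           index=list("vwxyz"), columns=list("abc"))
        lengths = pd.Series(rng.integers(100, 2000, size=5), index=mat.index)
        totals = pd.Series(rng.integers(1000, 9000, size=3), index=mat.columns)
        out = quantify.fpkm(mat, lengths, totals)
        for f in mat.index:
            for s in mat.columns:
                expect = mat.loc[f, s] / (lengths[f] / 1e3) / (totals[s] / 1e6)
                assert out.loc[f, s] == pytest.approx(expect, rel=1e-9)

    def test_zero_total_errors(self):
        mat = pd.DataFrame({"s": [1]}, index=["f"])
        with pytest.raises(ValueError, match="positive"):
            quantify.fpkm(mat, pd.Series({"f": 100}), {"s": 0})


class TestEnrichment:
    def test_identical_libraries_give_unit_fold_change(self):
        counts = pd.Series({"c1": 100, "g1": 80})
        lengths = pd.Series({"c1": 500, "g1": 900})
        classes = pd.Series({"c1": "circ", "g1": "mRNA"})
        table, _ = quantify.enrichment_fold_change(counts, counts, lengths, 1e6, 1e6, classes)
        assert np.allclose(table["fold_change"], 1.0)

    def test_two_fold_feature_within_five_percent(self):
        counts_u = pd.Series({"c1": 500})
        counts_t = pd.Series({"c1": 1000})
        lengths = pd.Series({"c1": 800})
        classes = pd.Series({"c1": "circ"})
        table, _ = quantify.enrichment_fold_change(counts_t, counts_u, lengths, 1e6, 1e6, classes)
        assert table.loc["c1", "fold_change"] == pytest.approx(2.0, rel=0.05)

    def test_rnase_r_depletion_enriches_circles(self):
        treated, untreated, lengths, classes = simulate_rnase_r_counts(
            n_circ=60, n_mrna=60, depletion=10.0, seed=5
        )
        table, report = quantify.enrichment_fold_change(
            treated, untreated, lengths, treated.sum(), untreated.sum(), classes
        )
        assert report["median_circ_fc"] > report["median_mrna_fc"]
        assert report["p_value"] < 1e-6

    def test_gene_universe_restriction(self):
        counts = pd.Series({"c1": 10, "g1": 10, "g2": 10})
        lengths = pd.Series({"c1": 500, "g1": 500, "g2": 500})
        classes = pd.Series({"c1": "circ", "g1": "mRNA", "g2": "mRNA"})
        table, _ = quantify.enrichment_fold_change(
            counts, counts, lengths, 1e6, 1e6, classes, genes_with_circ={"g1"}
        )
        assert set(table.index) == {"c1", "g1"}


class TestPrefilter:
    def test_boundary_rows(self):
        mat = pd.DataFrame([[3, 3, 3, 0], [3, 3, 2, 2]], index=["keep", "drop"],
                           columns=list("abcd"))
        out = quantify.prefilter_counts(mat)
        assert list(out.index) == ["keep"]

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.integers(0, 6, size=(50, 5)),
                           index=[f"r{i}" for i in range(50)], columns=list("abcde"))
        out = quantify.prefilter_counts(mat, min_count=3, min_samples=3)
        expect = [r for r in mat.index if sum(v >= 3 for v in mat.loc[r]) >= 3]
        assert list(out.index) == expect

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.integers(0, 6, size=(30, 4)), columns=list("abcd"))
        once = quantify.prefilter_counts(mat)
        twice = quantify.prefilter_counts(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_too_few_samples_errors(self):
        mat = pd.DataFrame([[5, 5]], columns=["a", "b"])
        with pytest.raises(ValueError, match="requires"):
            quantify.prefilter_counts(mat)


class TestZscoreLog2Cpm:
    def test_constant_row_maps_to_zero(self):
        mat = pd.DataFrame([[10, 10, 10], [1, 5, 9], [9, 5, 1]],
                           index=["const", "var", "balance"], columns=list("abc"))
        # equal column totals keep the first row's CPM constant
        out = quantify.zscore_log2cpm(mat)
        assert np.allclose(out.loc["const"], 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.integers(1, 500, size=(20, 6)), columns=list("abcdef"))
        out = quantify.zscore_log2cpm(mat)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        sds = out.std(axis=1, ddof=0)
        assert np.allclose(sds[sds > 0], 1.0, atol=1e-9)

    def test_matches_step_by_step_recomputation(self):
        mat = pd.DataFrame([[4, 8, 2], [1, 0, 3]], index=["r1", "r2"], columns=list("abc"))
        out = quantify.zscore_log2cpm(mat)
        cpm = mat / mat.sum(axis=0) * 1e6
        log = np.log2(cpm + 0.5)
        for r in mat.index:
            vals = log.loc[r]
            expect = (vals - vals.mean()) / vals.std(ddof=0)
            assert np.allclose(out.loc[r], expect, atol=1e-9)
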