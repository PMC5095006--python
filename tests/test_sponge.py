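"""miRNA seed-match scanning and E_circ sponge scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.sequtils import revcomp
from circkit.sponge import (
    average_e_circ,
    e_circ,
    e_circ_by_mirna,
    ecdf_table,
    find_seed_matches,
    seed_density,
)

# mature miRNA 5'->3'; seed (bases 2-7) = ACAUUC, extended seed (2-8) = ACAUUCC
MIRNA = "UACAUUCCUAGCUAGGAUCAUU"
SITE_7M8 = revcomp("ACATTCC")          # GGAATGT
SITE_8MER = SITE_7M8 + "A"             # GGAATGTA
SITE_7A1 = revcomp("ACATTC") + "A"     # GAATGTA


class TestFindSeedMatches:
    def test_empty_target(self):
        assert find_seed_matches("", MIRNA) == []

    def test_constructed_8mer_found_at_position(self):
        target = "CCCCC" + SITE_8MER + "CCCCC"
        matches = find_seed_matches(target, MIRNA)
        assert [(m.site_type, m.position) for m in matches if m.site_type == "8mer"] == [("8mer", 5)]

    def test_8mer_implies_internal_7mer_a1(self):
        # the 8mer's last 7 bases are themselves a 7mer-A1 site one position in
        target = "CCCCC" + SITE_8MER + "CCCCC"
        matches = find_seed_matches(target, MIRNA)
        assert {(m.site_type, m.position) for m in matches} == {("8mer", 5), ("7mer-A1", 6)}

    def test_site_hierarchy_strongest_reported_per_position(self):
        target = "CC" + SITE_7M8 + "CCCC"  # no trailing A -> 7mer-m8, not 8mer
        matches = find_seed_matches(target, MIRNA)
        assert [(m.site_type, m.position) for m in matches] == [("7mer-m8", 2)]

    def test_u_t_normalization_invariance(self):
        target_dna = "AA" + SITE_7A1 + "GG"
        target_rna = target_dna.replace("T", "U").lower()
        a = find_seed_matches(target_dna, MIRNA)
        b = find_seed_matches(target_rna, MIRNA)
        assert [(m.site_type, m.position) for m in a] == [(m.site_type, m.position) for m in b]
        assert a[0].site_type == "7mer-A1"

    def test_ambiguous_base_window_skipped(self):
        target = "CCCCC" + SITE_8MER[:4] + "N" + SITE_8MER[5:] + "CCCCC"
        assert find_seed_matches(target, MIRNA) == []

    def test_circular_wrap_finds_junction_straddling_site(self):
        # place the site across the end/start seam
        target = SITE_8MER[3:] + "CCCCCCCCCCCC" + SITE_8MER[:3]
        linear = find_seed_matches(target, MIRNA)
        circular = find_seed_matches(target, MIRNA, circular=True)
        assert all(m.site_type != "8mer" for m in linear)
        assert any(m.site_type == "8mer" and m.position == len(target) - 3 for m in circular)

    def test_matches_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        target = "".join(rng.choice(list("ACGT"), size=3000))
        mirnas = ["".join(rng.choice(list("ACGU"), size=22)) for _ in range(20)]

        def naive(target, mirna):
            m = mirna.replace("U", "T")
            pats = [("8mer", revcomp(m[1:8]) + "A"), ("7mer-m8", revcomp(m[1:8])),
                    ("7mer-A1", revcomp(m[1:7]) + "A")]
            found = []
            for pos in range(len(target)):
                for name, pat in pats:
                    if target[pos : pos + len(pat)] == pat and len(target) - pos >= len(pat):
                        found.append((name, pos))
                        break
            return found

        for i, mir in enumerate(mirnas):
            got = [(m.site_type, m.position) for m in find_seed_matches(target, mir, mirna_id=f"m{i}")]
            assert got == naive(target, mir)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            find_seed_matches("ACGTACGT", "ACGUACG")


class TestSeedDensity:
    def test_matches_per_kilobase(self):
        target = "C" * 492 + SITE_7M8 + "C" * 401 + SITE_7M8 + "C" * 93
        assert len(target) == 1000
        dens = seed_density({"t": target}, {"m": MIRNA})
        assert dens.loc["t", "n_matches"] == 2
        assert dens.loc["t", "density_per_kb"] == pytest.approx(2.0)

    def test_planted_sites_recovered(self):
        rng = np.random.default_rng(1)
        targets, expected = {}, {}
        for t in range(5):
            k = int(rng.integers(1, 6))
            # C-only background cannot form sites for this miRNA (seed needs G/A/T mix)
            chunks = ["C" * int(rng.integers(30, 80))]
            for _ in range(k):
                chunks += [SITE_8MER, "C" * int(rng.integers(30, 80))]
            targets[f"t{t}"] = "".join(chunks)
            expected[f"t{t}"] = 2 * k  # each 8mer also contains a 7mer-A1 one base in
        dens = seed_density(targets, {"m": MIRNA})
        for tid, n in expected.items():
            assert dens.loc[tid, "n_matches"] == n
            assert dens.loc[tid, "density_per_kb"] == pytest.approx(
                n * 1000 / len(targets[tid])
            )

    def test_class_labels_and_ecdf(self):
        targets = {"c1": "C" * 100 + SITE_8MER, "u1": "C" * 300}
        classes = {"c1": "circ", "u1": "3UTR"}
        dens = seed_density(targets, {"m": MIRNA}, target_class=classes)
        assert dens.loc["c1", "target_class"] == "circ"
        table = ecdf_table(dens["density_per_kb"])
        assert list(table["ecdf"]) == [0.5, 1.0]


class TestECirc:
    def test_single_circle(self):
        assert e_circ([(3, 2.0)]) == pytest.approx(6.0)

    def test_cancellation(self):
        assert e_circ([(2, 1.0), (1, -2.0)]) == pytest.approx(0.0, abs=1e-15)

    def test_empty_set_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            e_circ([])

    def test_matches_loop_summation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            pairs = [(int(rng.integers(0, 8)), float(rng.normal())) for _ in range(n)]
            total = 0.0
            for sites, fc in pairs:
                total += sites * fc
            assert e_circ(pairs) == pytest.approx(total / n, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 10),
                           st.floats(-50, 50, allow_nan=False)), min_size=1, max_size=8),
        st.floats(-4, 4, allow_nan=False),
    )
    def test_linear_in_fold_change(self, pairs, c):
        scaled = [(n, x * c) for n, x in pairs]
        assert e_circ(scaled) == pytest.approx(c * e_circ(pairs), abs=1e-9)

    def test_e_circ_by_mirna_drops_zero_site_edges(self):
        net = pd.DataFrame(
            {"circ_id": ["c1", "c2", "c3"], "mirna_id": ["m1", "m1", "m1"],
             "n_sites": [2, 0, 1], "log2fc": [1.0, 99.0, -2.0]}
        )
        out = e_circ_by_mirna(net)
        assert out["m1"] == pytest.approx((2 * 1.0 + 1 * -2.0) / 2)


class TestAverageECirc:
    def test_single_mirna_gene(self):
        edges = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"]})
        out = average_e_circ(edges, {"m1": 5.0})
        assert out["g1"] == pytest.approx(5.0)

    def test_mean_over_targeting_mirnas(self):
        edges = pd.DataFrame({"mirna_id": ["m1", "m2"], "gene_id": ["g1", "g1"]})
        out = average_e_circ(edges, {"m1": 1.0, "m2": 3.0})
        assert out["g1"] == pytest.approx(2.0)

    def test_gene_without_defined_scores_dropped(self):
        edges = pd.DataFrame({"mirna_id": ["mX"], "gene_id": ["g1"]})
        out = average_e_circ(edges, {"m1": 1.0})
        assert "g1" not in out.index

    def test_random_bipartite_network_oracle(self):
        rng = np.random.default_rng(3)
        mirnas = [f"m{i}" for i in range(10)]
        e_vals = {m: float(rng.normal()) for m in mirnas}
        rows = []
        for g in range(15):
            for m in rng.choice(mirnas, size=rng.integers(1, 5), replace=False):
                rows.append({"mirna_id": m, "gene_id": f"g{g}"})
        edges = pd.DataFrame(rows)
        out = average_e_circ(edges, e_vals)
        for g, grp in edges.groupby("gene_id"):
            vals = [e_vals[m] for m in sorted(set(grp["mirna_id"]))]
            assert out[g] == pytest.approx(sum(vals) / len(vals))
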