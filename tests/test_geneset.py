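"""SNP-to-gene assignment, set construction, LD matrix and the quadratic-form set test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eiphkit.geneset import (assign_snps_to_genes, build_gene_sets,
                             ld_correlation, quadform_tail_imhof,
                             quadform_tail_satterthwaite, set_intersections,
                             set_test)

from conftest import make_matrix


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chromosome",
                                       "start", "end", "tags"])


class TestAssignment:
    def _one_gene(self):
        return _genes([("g1", "GENE1", 1, 10_000, 20_000, "blood_flow")])

    def _map(self, positions, chrom=1):
        return pd.DataFrame({
            "snp_id": [f"S{i}" for i in range(len(positions))],
            "chromosome": [chrom] * len(positions),
            "position": positions,
        })

    def test_window_boundary_inclusive(self):
        mapping = assign_snps_to_genes(self._map([5_000]), self._one_gene(), window=5_000)
        assert mapping["GENE1"] == ["S0"]

    def test_one_bp_outside_window_excluded(self):
        mapping = assign_snps_to_genes(self._map([4_999]), self._one_gene(), window=5_000)
        assert mapping["GENE1"] == []

    def test_wrong_chromosome_excluded(self):
        mapping = assign_snps_to_genes(self._map([15_000], chrom=2),
                                       self._one_gene(), window=20_000)
        assert mapping["GENE1"] == []

    def test_matches_brute_force_double_loop(self, rng):
        snps = pd.DataFrame({
            "snp_id": [f"S{i}" for i in range(100)],
            "chromosome": rng.integers(1, 4, size=100),
            "position": rng.integers(1, 1_000_000, size=100),
        })
        genes = _genes([
            (f"g{i}", f"G{i}", int(rng.integers(1, 4)),
             int(s := rng.integers(1, 900_000)), int(s + rng.integers(1, 100_000)), "")
            for i in range(10)
        ])
        for window in (0, 5_000, 20_000):
            fast = assign_snps_to_genes(snps, genes, window=window)
            for _, g in genes.iterrows():
                brute = [r["snp_id"] for _, r in snps.iterrows()
                         if r["chromosome"] == g["chromosome"]
                         and g["start"] - window <= r["position"] <= g["end"] + window]
                assert sorted(fast[g["symbol"]]) == sorted(brute)

    def test_widening_window_never_loses_snps(self, small_cohort):
        genes = small_cohort["genes"].head(30)
        snp_map = small_cohort["matrix"].snp_map
        prev = None
        for window in (0, 5_000, 20_000):
            mapping = assign_snps_to_genes(snp_map, genes, window=window)
            count = {g: len(v) for g, v in mapping.items()}
            if prev is not None:
                assert all(count[g] >= prev[g] for g in count)
            prev = count


class TestSets:
    def _tagged(self):
        return _genes([
            ("g1", "A1", 1, 1, 2, "cell_cell_adhesion"),
            ("g2", "A2", 1, 3, 4, "cell_cell_adhesion,cytoskeleton,blood_flow"),
            ("g3", "A3", 1, 5, 6, "cytoskeleton"),
            ("g4", "A4", 1, 7, 8, ""),
        ])

    def test_tag_filtering_and_unknown_tag(self):
        sets = build_gene_sets(self._tagged(), tags=("cytoskeleton",))
        assert sets["cytoskeleton"] == ["A2", "A3"]
        with pytest.raises(ValueError, match="unknown tag"):
            build_gene_sets(self._tagged(), tags=("nonsense",))

    def test_fully_tagged_gene_in_every_set(self):
        sets = build_gene_sets(self._tagged(),
                               tags=("cell_cell_adhesion", "cytoskeleton", "blood_flow"))
        assert all("A2" in members for members in sets.values())

    def test_disjoint_sets_have_empty_intersections(self):
        sets = {"a": ["G1", "G2"], "b": ["G3"]}
        inter = set_intersections(sets, orders=(2,))
        assert inter["n_common"].tolist() == [0]

    def test_triple_intersection_of_five(self, small_cohort):
        sets = build_gene_sets(small_cohort["genes"])
        inter = set_intersections(sets)
        triple = inter[(inter["order"] == 3) &
                       (inter["sets"] == "blood_flow&cell_cell_adhesion&cytoskeleton")]
        assert triple["n_common"].iloc[0] == 5


class TestLD:
    def test_duplicated_column_correlation_one(self, rng):
        g = rng.integers(0, 3, size=(30, 1)).astype(float)
        m = make_matrix(np.hstack([g, g]))
        r = ld_correlation(m, ["S0", "S1"])
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self, rng):
        g = rng.binomial(2, 0.3, size=(10_000, 4)).astype(float)
        r = ld_correlation(make_matrix(g), [f"S{i}" for i in range(4)])
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_column_raises_naming_snp(self):
        m = make_matrix(np.column_stack([np.ones(10), np.tile([0.0, 1.0], 5)]))
        with pytest.raises(ValueError, match="S0"):
            ld_correlation(m, ["S0", "S1"])


class TestQuadraticFormNull:
    def test_single_snp_set_p_equals_snp_p(self):
        res = set_test([0.0123], np.eye(1), snp_ids=["S0"])
        assert res.p_value == pytest.approx(0.0123, abs=1e-6)

    def test_independent_snps_chi2_k_null(self):
        # R = I, k = 5: null is chi2_5; its 95th percentile is 11.0705
        t = stats.chi2.isf(0.05, df=5)
        assert t == pytest.approx(11.0705, abs=1e-3)
        p = quadform_tail_imhof(11.0705, np.ones(5))
        assert p == pytest.approx(0.0500, abs=2e-4)

    def test_imhof_matches_monte_carlo_correlated_block(self, rng):
        # block-exchangeable R, rho = 0.8, k = 10
        k, rho = 10, 0.8
        r = np.full((k, k), rho)
        np.fill_diagonal(r, 1.0)
        lam = np.linalg.eigvalsh(r)
        lam = lam[lam > 1e-8]
        draws = 200_000
        samples = (stats.chi2.rvs(1, size=(draws, lam.size), random_state=42)
                   * lam).sum(axis=1)
        for t in (5.0, 10.0, 20.0, 40.0):
            mc = float((samples > t).mean())
            se = np.sqrt(mc * (1 - mc) / draws)
            assert abs(quadform_tail_imhof(t, lam) - mc) < 3 * se + 1e-4

    def test_satterthwaite_close_to_imhof(self):
        lam = np.array([3.0, 1.0, 0.5, 0.5])
        t = 8.0
        assert quadform_tail_satterthwaite(t, lam) == pytest.approx(
            quadform_tail_imhof(t, lam), abs=0.02)

    def test_null_mean_equals_trace(self, rng):
        # sum of eigenvalues = trace(R) = k: the null mean of T
        g = rng.binomial(2, 0.4, size=(200, 6)).astype(float)
        r = ld_correlation(make_matrix(g), [f"S{i}" for i in range(6)])
        lam = np.linalg.eigvalsh(r)
        assert lam.sum() == pytest.approx(6.0, abs=1e-8)


class TestSetTest:
    def test_invariant_to_snp_reordering(self, rng):
        k = 8
        g = rng.binomial(2, 0.3, size=(100, k)).astype(float)
        m = make_matrix(g)
        ids = [f"S{i}" for i in range(k)]
        p = rng.random(k)
        r = ld_correlation(m, ids)
        res1 = set_test(p, r, snp_ids=ids)
        perm = rng.permutation(k)
        r_perm = ld_correlation(m, [ids[i] for i in perm])
        res2 = set_test(p[perm], r_perm, snp_ids=[ids[i] for i in perm])
        assert res1.p_value == pytest.approx(res2.p_value, rel=1e-6)
        assert res1.chi_square_observed == pytest.approx(res2.chi_square_observed)

    def test_result_schema_row(self):
        res = set_test([0.5, 0.01], np.eye(2), snp_ids=["a", "b"], set_name="demo",
                       n_genes=2)
        row = res.to_row()
        assert row["Top SNP"] == "b" and row["Top SNP p-Value"] == 0.01
        assert row["No SNPs"] == 2 and row["No Genes"] == 2
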