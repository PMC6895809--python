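"""EM haplotype frequencies, haplotype association, epistasis scan."""

import itertools

import numpy as np
import pytest

from eiphkit.haplo import (em_haplotype_freqs, epistasis_scan, haplotype_assoc,
                           pairs_between_genes)

from conftest import make_matrix


def block_loglik(freq_by_hap, genotypes):
    """Direct likelihood of genotype data given haplotype frequencies."""
    ll = 0.0
    for g in genotypes:
        tot = 0.0
        for h1 in itertools.product((0, 1), repeat=len(g)):
            h2 = tuple(a - b for a, b in zip(g, h1))
            if any(x not in (0, 1) for x in h2):
                continue
            tot += freq_by_hap.get(h1, 0.0) * freq_by_hap.get(h2, 0.0)
        ll += np.log(max(tot, 1e-300))
    return ll


class TestEM:
    def test_no_phase_ambiguity_gives_gamete_counts(self):
        # no double heterozygote: haplotypes countable directly
        calls = np.array([[2.0, 0.0], [0.0, 2.0], [2.0, 2.0], [0.0, 0.0]])
        block = em_haplotype_freqs(make_matrix(calls))
        freqs = dict(zip(block.haplotypes, block.frequencies))
        assert freqs[(1, 0)] == pytest.approx(0.25, abs=1e-6)
        assert freqs[(0, 1)] == pytest.approx(0.25, abs=1e-6)
        assert freqs[(1, 1)] == pytest.approx(0.25, abs=1e-6)
        assert freqs[(0, 0)] == pytest.approx(0.25, abs=1e-6)

    def test_frequencies_sum_to_one_and_dosages_to_two(self, rng):
        calls = rng.integers(0, 3, size=(20, 3)).astype(float)
        block = em_haplotype_freqs(make_matrix(calls))
        assert block.frequencies.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(np.nansum(block.dosages, axis=1), 2.0)

    def test_loglik_nondecreasing(self, rng):
        calls = rng.integers(0, 3, size=(25, 4)).astype(float)
        block = em_haplotype_freqs(make_matrix(calls))
        assert np.all(np.diff(block.loglik_path) > -1e-9)

    def test_em_dominates_random_frequency_vectors(self, rng):
        # EM fixed point beats 1,000 random frequency vectors in likelihood
        calls = rng.integers(0, 3, size=(20, 2)).astype(float)
        block = em_haplotype_freqs(make_matrix(calls))
        geno = [tuple(int(v) for v in row) for row in calls]
        em_ll = block_loglik(dict(zip(block.haplotypes, block.frequencies)), geno)
        all_haps = list(itertools.product((0, 1), repeat=2))
        for _ in range(1000):
            f = rng.dirichlet(np.ones(4))
            assert em_ll >= block_loglik(dict(zip(all_haps, f)), geno) - 1e-9

    def test_matches_enumeration_ml_small_sample(self, rng):
        # <= 8 individuals, 2 SNPs: grid over the frequency simplex
        calls = rng.integers(0, 3, size=(8, 2)).astype(float)
        block = em_haplotype_freqs(make_matrix(calls), tol=1e-12, max_iter=2000)
        geno = [tuple(int(v) for v in row) for row in calls]
        all_haps = list(itertools.product((0, 1), repeat=2))
        em_ll = block_loglik(dict(zip(block.haplotypes, block.frequencies)), geno)
        # dense simplex grid
        best = -np.inf
        steps = np.linspace(0, 1, 41)
        for f1 in steps:
            for f2 in steps:
                for f3 in steps:
                    f4 = 1 - f1 - f2 - f3
                    if f4 < -1e-12:
                        continue
                    ll = block_loglik(dict(zip(all_haps, (f1, f2, f3, max(f4, 0)))), geno)
                    best = max(best, ll)
        assert em_ll >= best - 1e-4

    def test_missing_block_calls_excluded(self):
        calls = np.array([[2.0, 0.0], [np.nan, 1.0], [0.0, 2.0]])
        block = em_haplotype_freqs(make_matrix(calls))
        assert np.isnan(block.dosages[1]).all()
        assert np.isfinite(block.dosages[0]).all()

    def test_block_cap_enforced(self, rng):
        calls = rng.integers(0, 3, size=(5, 13)).astype(float)
        with pytest.raises(ValueError, match="cap"):
            em_haplotype_freqs(make_matrix(calls))


class TestHaplotypeAssoc:
    def test_recovers_planted_haplotype_effect(self, rng):
        n = 500
        # two-SNP block built from explicit haplotypes
        hap_pool = [(0, 0), (1, 0), (0, 1), (1, 1)]
        probs = [0.4, 0.25, 0.2, 0.15]
        idx = rng.choice(4, size=(n, 2), p=probs)
        h = np.array(hap_pool)[idx]          # n x 2 haplotypes x 2 snps
        calls = h.sum(axis=1).astype(float)
        copies_11 = (idx == 3).sum(axis=1)
        delta = 1.0
        y = delta * copies_11 + rng.standard_normal(n) * 2.0
        block = em_haplotype_freqs(make_matrix(calls))
        tab = haplotype_assoc(y, block)
        row = tab[tab["haplotype"].str.len() == 2].set_index("haplotype")
        hap_str = block.haplotype_string(block.haplotypes.index((1, 1)))
        beta = row.loc[hap_str, "beta"]
        assert abs(beta - delta) < 0.3 * delta

    def test_complementary_haplotypes_equal_opposite_betas(self, rng):
        # 1-SNP block: two haplotypes with dosages d and 2-d
        calls = rng.integers(0, 3, size=(60, 1)).astype(float)
        y = 0.5 * calls[:, 0] + rng.standard_normal(60)
        block = em_haplotype_freqs(make_matrix(calls))
        tab = haplotype_assoc(y, block, min_freq=0.0)
        betas = tab["beta"].to_numpy()
        assert betas[0] == pytest.approx(-betas[1], rel=1e-9)
        assert tab["p_value"].iloc[0] == pytest.approx(tab["p_value"].iloc[1], rel=1e-9)

    def test_rare_haplotypes_skipped(self, rng):
        calls = rng.integers(0, 3, size=(30, 2)).astype(float)
        block = em_haplotype_freqs(make_matrix(calls))
        tab = haplotype_assoc(rng.standard_normal(30), block, min_freq=0.5)
        assert (tab["frequency"] >= 0.5).all()


class TestEpistasis:
    def test_pure_interaction_recovered(self, rng):
        g1 = rng.integers(0, 3, size=200).astype(float)
        g2 = rng.integers(0, 3, size=200).astype(float)
        m = make_matrix(np.column_stack([g1, g2]))
        res = epistasis_scan(g1 * g2, m, [("S0", "S1")])
        assert res["beta_interaction"].iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert res["p_value"].iloc[0] < 1e-20

    def test_constant_interaction_term_flagged(self):
        m = make_matrix(np.column_stack([np.tile([0.0, 1.0], 5), np.zeros(10)]))
        res = epistasis_scan(np.arange(10.0), m, [("S0", "S1")])
        assert np.isnan(res["p_value"].iloc[0])
        assert "constant" in res["note"].iloc[0]

    def test_edge_list_symmetric_in_pair_order(self, rng):
        g = rng.integers(0, 3, size=(100, 2)).astype(float)
        y = rng.standard_normal(100)
        m = make_matrix(g)
        a = epistasis_scan(y, m, [("S0", "S1")])
        b = epistasis_scan(y, m, [("S1", "S0")])
        assert a["p_value"].iloc[0] == pytest.approx(b["p_value"].iloc[0], rel=1e-9)

    def test_planted_interaction_graph_recovered(self, rng):
        # five "genes" of one SNP each; interactions planted on two edges
        n = 400
        g = rng.integers(0, 3, size=(n, 5)).astype(float)
        m = make_matrix(g)
        y = (g[:, 0] * g[:, 1] + g[:, 2] * g[:, 3]) * 0.8 + rng.standard_normal(n)
        gene2snps = {f"G{i}": [f"S{i}"] for i in range(5)}
        pairs, labels = pairs_between_genes(gene2snps, [f"G{i}" for i in range(5)])
        res = epistasis_scan(y, m, pairs, p_threshold=0.05 / len(pairs))
        sig = set()
        for (_, row), (ga, gb) in zip(res.iterrows(), labels):
            if row["significant"]:
                sig.add((ga, gb))
        assert sig == {("G0", "G1"), ("G2", "G3")}

    def test_additive_model_null_calibration(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            g1 = rng.integers(0, 3, size=120).astype(float)
            g2 = rng.integers(0, 3, size=120).astype(float)
            y = 0.5 * g1 - 0.3 * g2 + rng.standard_normal(120)
            m = make_matrix(np.column_stack([g1, g2]))
            res = epistasis_scan(y, m, [("S0", "S1")])
            rejections += bool(res["p_value"].iloc[0] < 0.05)
        # binomial 95% CI around 0.05 at 200 replicates
        assert abs(rejections / n_rep - 0.05) < 0.035
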