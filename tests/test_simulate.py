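"""Synthetic cohort generator: determinism, LD, family structure, tag scheme, cytology link."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eiphkit.simulate import (SET_SIZES, SimConfig, simulate_cohort,
                              simulate_cytology_series,
                              simulate_gene_annotation, simulate_genotypes,
                              simulate_phenotype, write_cohort)


class TestGenotypes:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_snps=500, seed=7)
        a, fa = simulate_genotypes(cfg)
        b, fb = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.calls, b.calls)
        np.testing.assert_array_equal(fa, fb)
        pd.testing.assert_frame_equal(a.snp_map, b.snp_map)

    def test_cohort_composition(self):
        m, fams = simulate_genotypes(SimConfig(n_snps=200, seed=1))
        assert m.n_individuals == 72
        assert (np.asarray(m.sexes) == "M").sum() == 32
        assert (np.asarray(m.sexes) == "F").sum() == 40
        assert sorted(np.unique(fams)) == [0, 1, 2, 3]
        assert (fams > 0).sum() == 24

    def test_snp_density_and_chromosomes(self):
        m, _ = simulate_genotypes(SimConfig(n_snps=620, n_chromosomes=31, seed=2))
        sm = m.snp_map
        assert sm["chromosome"].nunique() == 31
        gaps = sm.groupby("chromosome")["position"].diff().dropna()
        assert (gaps == 43_200).all()

    def test_empirical_mafs_near_targets(self):
        cfg = SimConfig(n_individuals=1000, n_male=500, n_families=0,
                        family_size=1, n_snps=300, seed=3)
        m, _ = simulate_genotypes(cfg)
        freqs = np.nanmean(m.calls, axis=0) / 2
        mafs = np.minimum(freqs, 1 - freqs)
        # targets are uniform on [0.05, 0.5]; check the folded empirical
        # frequency stays in a sampling-consistent band
        assert mafs.min() > 0.01
        assert np.mean((mafs > 0.04) & (mafs <= 0.5)) > 0.95

    def test_zero_rho_gives_near_independent_adjacent_snps(self):
        cfg = SimConfig(n_individuals=2500, n_male=1250, n_families=0,
                        family_size=1, n_snps=200, within_block_rho=0.0, seed=4)
        m, _ = simulate_genotypes(cfg)
        g = pd.DataFrame(m.calls)
        r = np.array([g[j].corr(g[j + 1]) for j in range(199)])
        assert np.nanmean(np.abs(r)) < 0.05

    def test_positive_rho_creates_ld_blocks(self):
        cfg = SimConfig(n_individuals=400, n_male=200, n_families=0, family_size=1,
                        n_snps=100, within_block_rho=0.9, ld_block_len=10, seed=5)
        m, _ = simulate_genotypes(cfg)
        g = pd.DataFrame(m.calls)
        within = [abs(g[j].corr(g[j + 1])) for j in range(9)]
        assert np.mean(within) > 0.4

    def test_half_sibs_more_related_than_background(self):
        m, fams = simulate_genotypes(SimConfig(n_snps=800, seed=6))
        from eiphkit.structure import ibs_matrix
        ibs = ibs_matrix(m)
        fam1 = np.flatnonzero(fams == 1)
        bg = np.flatnonzero(fams == 0)
        within = np.mean([ibs[i, j] for i in fam1 for j in fam1 if i < j])
        across = np.mean([ibs[i, j] for i in fam1[:4] for j in bg[:12]])
        assert within > across + 0.01


class TestAnnotation:
    def test_set_sizes_match_study_scale(self, small_cohort):
        genes = small_cohort["genes"]
        from eiphkit.geneset import build_gene_sets
        sets = build_gene_sets(genes)
        assert {k: len(v) for k, v in sets.items()} == SET_SIZES

    def test_gene_spans_contain_snps_and_stay_on_one_chromosome(self, small_cohort):
        genes = small_cohort["genes"]
        snp_map = small_cohort["matrix"].snp_map
        from eiphkit.geneset import assign_snps_to_genes
        mapping = assign_snps_to_genes(snp_map, genes, window=0)
        n_with = sum(bool(v) for v in mapping.values())
        assert n_with == len(genes)
        assert (genes["start"] <= genes["end"]).all()

    def test_inconsistent_intersections_raise(self):
        cfg = SimConfig(n_snps=3000,
                        intersections={("blood_flow", "cytoskeleton"): 999})
        m, _ = simulate_genotypes(SimConfig(n_snps=3000, seed=0))
        with pytest.raises(ValueError, match="exceed"):
            simulate_gene_annotation(cfg, m.snp_map)

    def test_non_overlapping_spans(self, small_cohort):
        genes = small_cohort["genes"].sort_values(["chromosome", "start"])
        for _, grp in genes.groupby("chromosome"):
            starts = grp["start"].to_numpy()[1:]
            ends = grp["end"].to_numpy()[:-1]
            assert (starts > ends).all()


class TestPhenotype:
    def test_truth_lists_exactly_the_causal_snps(self, small_cohort):
        truth = small_cohort["truth"]
        assert len(truth) == 4  # two causal SNPs per causal set
        assert set(truth["set"]) == {"cytoskeleton", "blood_flow"}
        snp_ids = set(small_cohort["matrix"].snp_ids)
        assert set(truth["snp_id"]) <= snp_ids

    def test_h2_zero_gives_unassociated_phenotype(self):
        cfg = SimConfig(n_snps=2000, h2=0.0, seed=8)
        m, _ = simulate_genotypes(cfg)
        genes = simulate_gene_annotation(cfg, m.snp_map)
        y, score, truth = simulate_phenotype(m, genes, cfg)
        assert np.all(score == 0) and np.all(truth["effect"] == 0)
        from eiphkit.assoc import SNPAssociationModel
        lam = SNPAssociationModel(y, m).fit().genomic_inflation()
        assert 0.8 < lam < 1.2

    def test_h2_zero_with_explicit_effect_raises(self):
        cfg = SimConfig(n_snps=2000, h2=0.0, effect_size=1.0, seed=8)
        m, _ = simulate_genotypes(cfg)
        genes = simulate_gene_annotation(cfg, m.snp_map)
        with pytest.raises(ValueError, match="inconsistent"):
            simulate_phenotype(m, genes, cfg)

    def test_realized_h2_near_target(self):
        cfg = SimConfig(n_individuals=2000, n_male=1000, n_families=0,
                        family_size=1, n_snps=3000, h2=0.5, seed=9)
        m, _ = simulate_genotypes(cfg)
        genes = simulate_gene_annotation(cfg, m.snp_map)
        y, score, _ = simulate_phenotype(m, genes, cfg)
        realized = np.var(score) / np.var(y)
        assert realized == pytest.approx(0.5, abs=0.05)


class TestCytology:
    def test_zero_bleed_probability_all_background(self):
        cfg = SimConfig(n_individuals=20, n_male=10, n_families=0, family_size=1,
                        bleed_intercept=-100.0, seed=10)
        cyt, _ = simulate_cytology_series(np.zeros(20), cfg)
        assert set(cyt["haemosiderophages"].unique()) <= {0, 1}

    def test_certain_weekly_bleeding_saturates(self):
        cfg = SimConfig(n_individuals=10, n_male=5, n_families=0, family_size=1,
                        bleed_intercept=100.0, seed=11)
        cyt, _ = simulate_cytology_series(np.zeros(10), cfg)
        from eiphkit.cytology import hf_frequency_score
        scores = cyt.groupby("horse_id")["haemosiderophages"].apply(
            lambda s: hf_frequency_score(s))
        assert (scores > 0.9).all()

    def test_risk_score_drives_hf_frequency(self, small_cohort):
        from eiphkit.cytology import hf_frequency_score
        cyt = small_cohort["cytology"]
        scores = cyt.groupby("horse_id")["haemosiderophages"].apply(
            lambda s: hf_frequency_score(s))
        risk = pd.Series(small_cohort["score"],
                         index=small_cohort["matrix"].individuals)
        rho, p = stats.spearmanr(scores, risk.loc[scores.index])
        assert rho > 0 and p < 0.01

    def test_race_records_well_formed(self, small_cohort):
        races = small_cohort["races"]
        assert len(races) == 72
        assert (pd.to_datetime(races["last_start"])
                >= pd.to_datetime(races["first_start"])).all()
        assert set(races["gender"]) == {"male", "female"}


def test_write_cohort_emits_every_input_format(tmp_path, small_cohort):
    paths = write_cohort(small_cohort, tmp_path)
    for key in ("ped", "map", "cytology", "races", "genes", "sets", "truth"):
        assert (tmp_path / paths[key].split("/")[-1]).exists()
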