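"""EM haplotype-frequency estimation, haplotype-phenotype regression, and epistasis scans.

Unphased dosage genotypes over a small block of SNPs (<= 12) are
resolved into haplotype frequencies by the classical EM algorithm: the
E-step weights every haplotype pair compatible with an individual's
multilocus genotype by the product of current frequencies
(Hardy-Weinberg pairing), and the M-step re-estimates frequencies from
the posterior-expected haplotype counts.  The per-individual expected
haplotype dosages from the final posteriors feed a per-haplotype
(one-vs-rest) linear regression on the phenotype.

Epistasis between two SNPs is tested by the interaction term of
y ~ 1 + g1 + g2 + g1*g2 (+ covariates), two-sided t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import _ols_snp
from .genio import GenotypeMatrix

MAX_BLOCK_SNPS = 12


@dataclass
class HaplotypeBlock:
    """EM output for one SNP block."""

    snp_ids: list
    haplotypes: list            # tuples of 0/1 per SNP (1 = minor allele)
    frequencies: np.ndarray     # sums to 1
    dosages: np.ndarray         # n_individuals x n_haplotypes, rows sum to 2 (NaN if unresolvable)
    loglik_path: list = field(default_factory=list)
    converged: bool = True
    allele_labels: list | None = None  # per-SNP (minor, major) letters for display

    def haplotype_string(self, idx: int) -> str:
        """Display string for haplotype ``idx`` using allele letters when known."""
        hap = self.haplotypes[idx]
        if self.allele_labels:
            return "".join(self.allele_labels[j][0] if a == 1 else self.allele_labels[j][1]
                           for j, a in enumerate(hap))
        return "".join("A" if a == 1 else "B" for a in hap)


def _compatible_pairs(genotype: tuple[int, ...]):
    """All ordered haplotype pairs (h1, h2) with h1 + h2 == genotype."""
    het = [j for j, g in enumerate(genotype) if g == 1]
    base1 = [g // 2 if g != 1 else 0 for g in genotype]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het)):
        h1 = list(base1)
        for j, b in zip(het, bits):
            h1[j] = b
        h2 = tuple(g - a for g, a in zip(genotype, h1))
        pairs.append((tuple(h1), h2))
    return pairs


def em_haplotype_freqs(matrix: GenotypeMatrix, snp_ids=None, max_iter: int = 200,
                       tol: float = 1e-8, seed: int | None = None) -> HaplotypeBlock:
    """EM haplotype frequencies for a block of up to 12 SNPs.

    Initialization is the linkage-equilibrium product of allele
    frequencies (deterministic); ``seed`` is reserved for optional
    random restarts and unused by the default start.  Individuals with a
    missing call inside the block are excluded from estimation and get
    NaN dosages.  The log-likelihood is non-decreasing per iteration.
    """
    sub = matrix if snp_ids is None else matrix.subset_snps(list(snp_ids))
    ids = list(sub.snp_map["snp_id"])
    if snp_ids is not None:  # preserve requested order
        order = {s: i for i, s in enumerate(ids)}
        perm = [order[s] for s in snp_ids]
        calls = sub.calls[:, perm]
        ids = list(snp_ids)
        labels = [(sub.snp_map["allele_a"].iloc[perm[j]], sub.snp_map["allele_b"].iloc[perm[j]])
                  if "allele_a" in sub.snp_map else None for j in range(len(perm))]
    else:
        calls = sub.calls
        labels = [(r["allele_a"], r["allele_b"]) if "allele_a" in sub.snp_map else None
                  for _, r in sub.snp_map.iterrows()]
    m = calls.shape[1]
    if m > MAX_BLOCK_SNPS:
        raise ValueError(f"block of {m} SNPs exceeds the {MAX_BLOCK_SNPS}-SNP cap")
    if any(l is None for l in labels):
        labels = None

    usable = ~np.isnan(calls).any(axis=1)
    geno = calls[usable].astype(int)
    if geno.shape[0] == 0:
        raise ValueError("no individual has complete calls in the block")

    pairs_per_ind = [_compatible_pairs(tuple(g)) for g in geno]
    hap_index: dict[tuple, int] = {}
    for pairs in pairs_per_ind:
        for h1, h2 in pairs:
            hap_index.setdefault(h1, len(hap_index))
            hap_index.setdefault(h2, len(hap_index))
    haps = sorted(hap_index, key=lambda h: hap_index[h])
    hap_index = {h: i for i, h in enumerate(haps)}
    k = len(haps)

    # linkage-equilibrium start from per-SNP allele frequencies
    p_allele = geno.mean(axis=0) / 2.0
    p_allele = np.clip(p_allele, 1e-6, 1 - 1e-6)
    freqs = np.array([
        np.prod([p_allele[j] if h[j] == 1 else 1 - p_allele[j] for j in range(m)])
        for h in haps
    ])
    freqs /= freqs.sum()

    idx_pairs = [np.array([(hap_index[a], hap_index[b]) for a, b in pairs])
                 for pairs in pairs_per_ind]
    n_use = geno.shape[0]
    loglik_path = []
    converged = False
    for _ in range(max_iter):
        counts = np.zeros(k)
        ll = 0.0
        for pairs in idx_pairs:
            w = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
            tot = w.sum()
            ll += np.log(max(tot, 1e-300))
            post = w / max(tot, 1e-300)
            np.add.at(counts, pairs[:, 0], post)
            np.add.at(counts, pairs[:, 1], post)
        loglik_path.append(ll)
        new = counts / (2 * n_use)
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("haplotype EM did not converge; returning last iterate")

    # expected dosages from final posteriors
    dosages = np.full((matrix.n_individuals if snp_ids is None else sub.n_individuals, k), np.nan)
    rows = np.flatnonzero(usable)
    for r, pairs in zip(rows, idx_pairs):
        w = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
        tot = max(w.sum(), 1e-300)
        post = w / tot
        d = np.zeros(k)
        np.add.at(d, pairs[:, 0], post)
        np.add.at(d, pairs[:, 1], post)
        dosages[r] = d

    return HaplotypeBlock(snp_ids=ids, haplotypes=haps, frequencies=freqs,
                          dosages=dosages, loglik_path=loglik_path,
                          converged=converged, allele_labels=labels)


def haplotype_assoc(phenotype, block: HaplotypeBlock, covariates=None,
                    min_freq: float = 0.01, chromosome=None, bp_span=None,
                    gene: str = "") -> pd.DataFrame:
    """Per-haplotype (one-vs-rest) regression of the phenotype on expected dosage.

    Haplotypes below ``min_freq`` are skipped.  Returns a table in the
    reporting schema (chromosome, bp span, gene, haplotype string, beta,
    p-value) plus the estimated frequency.
    """
    y = np.asarray(phenotype, dtype=float)
    cov = (np.asarray(covariates, dtype=float) if covariates is not None
           else np.empty((y.size, 0)))
    if cov.ndim == 1:
        cov = cov[:, None]
    rows = []
    for h in range(len(block.haplotypes)):
        f = block.frequencies[h]
        if f < min_freq:
            continue
        d = block.dosages[:, h]
        use = np.isfinite(d) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
        beta, se, t, p, n = _ols_snp(y[use], d[use], cov[use])
        rows.append({
            "chromosome": chromosome, "bp_span": bp_span, "gene": gene,
            "haplotype": block.haplotype_string(h), "frequency": float(f),
            "beta": beta, "p_value": p, "n_used": n,
        })
    columns = ["chromosome", "bp_span", "gene", "haplotype", "frequency",
               "beta", "p_value", "n_used"]
    return pd.DataFrame(rows, columns=columns)


def epistasis_scan(phenotype, matrix: GenotypeMatrix, snp_pairs,
                   covariates=None, p_threshold: float = 0.05) -> pd.DataFrame:
    """Pairwise SNP x SNP interaction scan.

    For each (snp_1, snp_2) pair fits y ~ 1 + g1 + g2 + g1*g2
    (+ covariates) on complete cases and tests the interaction
    coefficient.  Returns one row per pair with the interaction beta,
    p-value, marginal betas, and a ``significant`` flag at
    ``p_threshold`` (nominal, as in edge-list reporting); a
    Bonferroni-adjusted p over the scanned pairs is also given.
    """
    y = np.asarray(phenotype, dtype=float)
    cov = (np.asarray(covariates, dtype=float) if covariates is not None
           else np.empty((y.size, 0)))
    if cov.ndim == 1:
        cov = cov[:, None]
    rows = []
    for s1, s2 in snp_pairs:
        g1, g2 = matrix.column(s1), matrix.column(s2)
        use = (np.isfinite(g1) & np.isfinite(g2) & np.isfinite(y)
               & np.all(np.isfinite(cov), axis=1))
        inter = g1[use] * g2[use]
        if np.ptp(inter) == 0:
            rows.append({"snp_1": s1, "snp_2": s2, "beta_interaction": np.nan,
                         "p_value": np.nan, "beta_1": np.nan, "beta_2": np.nan,
                         "n_used": int(use.sum()), "note": "constant interaction term"})
            continue
        others = np.column_stack([g1[use], g2[use], cov[use]])
        beta_i, se, t, p, n = _ols_snp(y[use], inter, others)
        beta_1, *_ = _ols_snp(y[use], g1[use], np.column_stack([g2[use], cov[use]]))
        beta_2, *_ = _ols_snp(y[use], g2[use], np.column_stack([g1[use], cov[use]]))
        rows.append({"snp_1": s1, "snp_2": s2, "beta_interaction": beta_i,
                     "p_value": p, "beta_1": beta_1, "beta_2": beta_2,
                     "n_used": n, "note": ""})
    out = pd.DataFrame(rows)
    m = int(out["p_value"].notna().sum())
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(m, 1), 1.0)
    out["significant"] = out["p_value"] < p_threshold
    return out


def pairs_between_genes(gene_to_snps: dict[str, list[str]], genes=None):
    """Cross-gene SNP pairs (with gene labels) for an epistasis edge list."""
    names = list(genes) if genes is not None else sorted(gene_to_snps)
    pairs, labels = [], []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            for s1 in gene_to_snps.get(ga, []):
                for s2 in gene_to_snps.get(gb, []):
                    pairs.append((s1, s2))
                    labels.append((ga, gb))
    return pairs, labels


def gene_haplotype_blocks(matrix: GenotypeMatrix, genes: pd.DataFrame,
                          window: int = 0, max_snps: int = MAX_BLOCK_SNPS):
    """Define one haplotype block per gene from the SNPs spanning it.

    Returns a list of (gene row, snp id list); genes with no SNPs are
    skipped, genes with more than ``max_snps`` SNPs keep the first
    ``max_snps`` by position.
    """
    from .geneset import assign_snps_to_genes

    gene2snps = assign_snps_to_genes(matrix.snp_map, genes, window=window)
    blocks = []
    pos = matrix.snp_map.set_index("snp_id")["position"]
    for _, g in genes.iterrows():
        snps = gene2snps.get(g["symbol"], [])
        if not snps:
            continue
        snps = sorted(snps, key=lambda s: pos[s])[:max_snps]
        blocks.append((g, snps))
    return blocks
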